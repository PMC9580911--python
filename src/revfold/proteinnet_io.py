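"""Readers/writers for the ProteinNet text dialect and standard output formats.

A ProteinNet text record is a sequence of bracketed sections::

    [ID]            one identifier line
    [PRIMARY]       the residue string
    [EVOLUTIONARY]  21 tab-separated numeric rows of length n
                    (20 residue-frequency rows + 1 information-content row)
    [TERTIARY]      3 rows (x, y, z) of length 3n — N, Cα, C' per residue,
                    in picometers
    [MASK]          a length-n string of '+'/'-'

Only the Cα atom and the 20 frequency rows are carried into
:class:`~revfold.core.ProteinRecord`; coordinates are converted pm → Å (÷100).
Writers synthesize N and C' coincident with Cα (the id line is flagged
``CA_ONLY``) so written fixtures remain parseable by the same reader.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, ProteinRecord, onehot_to_sequence

_CA_FLAG = " CA_ONLY"
_SECTIONS = ("[ID]", "[PRIMARY]", "[EVOLUTIONARY]", "[TERTIARY]", "[MASK]")

# pm per Å: ProteinNet stores coordinates in picometers
_PM_PER_ANGSTROM = 100.0


class ProteinNetFormatError(ValueError):
    pass


def _parse_floats(line: str, record_id: str, lineno: int) -> list[float]:
    try:
        return [float(tok) for tok in line.split()]
    except ValueError as exc:
        raise ProteinNetFormatError(
            f"record {record_id!r}, line {lineno}: unparseable number ({exc})"
        ) from None


def read_proteinnet(path, max_length: int = 1000,
                    residue_order: str = AMINO_ACIDS) -> list[ProteinRecord]:
    """Parse a ProteinNet text file into validated records.

    Records longer than ``max_length`` residues are dropped (the standard
    benchmark filter).  ``residue_order`` gives the residue ordering of the
    [EVOLUTIONARY] rows; rows are re-indexed to the package's canonical
    alphabetical order.  PSSM columns are renormalized only when their sum
    drifts from 1 by more than the record tolerance (1e-5).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    perm = [residue_order.index(aa) for aa in AMINO_ACIDS]

    records: list[ProteinRecord] = []
    i = 0
    nlines = len(lines)
    while i < nlines:
        if lines[i].strip() != "[ID]":
            if lines[i].strip() == "":
                i += 1
                continue
            raise ProteinNetFormatError(f"line {i + 1}: expected [ID], got {lines[i]!r}")
        sections: dict[str, tuple[int, list[str]]] = {}
        current = "[ID]"
        start = i + 1
        body: list[str] = []
        i += 1
        while i < nlines and lines[i].strip() != "[ID]":
            stripped = lines[i].strip()
            if stripped in _SECTIONS:
                sections[current] = (start, body)
                current, start, body = stripped, i + 1, []
            elif stripped:
                body.append(lines[i])
            i += 1
        sections[current] = (start, body)
        records_id_lines = sections.get("[ID]", (0, []))[1]
        rec_id = records_id_lines[0].strip() if records_id_lines else "?"
        if rec_id.endswith(_CA_FLAG.strip()):
            rec_id = rec_id[: -len(_CA_FLAG.strip())].rstrip()
        missing = [s for s in _SECTIONS if s not in sections]
        if missing:
            raise ProteinNetFormatError(
                f"record {rec_id!r}: missing sections {missing}")

        lineno, primary = sections["[PRIMARY]"]
        sequence = primary[0].strip() if primary else ""
        n = len(sequence)

        lineno, evo = sections["[EVOLUTIONARY]"]
        if len(evo) != 21:
            raise ProteinNetFormatError(
                f"record {rec_id!r}, line {lineno + 1}: expected 21 evolutionary "
                f"rows, got {len(evo)}")
        evo_rows = [_parse_floats(row, rec_id, lineno + 1 + k)
                    for k, row in enumerate(evo)]
        if any(len(r) != n for r in evo_rows):
            raise ProteinNetFormatError(
                f"record {rec_id!r}, line {lineno + 1}: evolutionary row length "
                f"!= sequence length {n}")
        pssm = np.array(evo_rows[:20])[perm]  # information-content row dropped
        sums = pssm.sum(axis=0)
        drift = np.abs(sums - 1.0) > 1e-5
        if drift.any():
            safe = np.where(sums > 0, sums, 1.0)
            pssm = np.where(drift, pssm / safe, pssm)

        lineno, tert = sections["[TERTIARY]"]
        if len(tert) != 3:
            raise ProteinNetFormatError(
                f"record {rec_id!r}, line {lineno + 1}: expected 3 tertiary rows")
        tert_rows = [_parse_floats(row, rec_id, lineno + 1 + k)
                     for k, row in enumerate(tert)]
        if any(len(r) != 3 * n for r in tert_rows):
            raise ProteinNetFormatError(
                f"record {rec_id!r}, line {lineno + 1}: tertiary rows must have "
                f"3n = {3 * n} values")
        # the Cα atom is the second of each residue's (N, Cα, C') triplet
        coords = np.array(tert_rows)[:, 1::3] / _PM_PER_ANGSTROM

        lineno, mask_lines = sections["[MASK]"]
        mask_str = mask_lines[0].strip() if mask_lines else ""
        if len(mask_str) != n or set(mask_str) - {"+", "-"}:
            raise ProteinNetFormatError(
                f"record {rec_id!r}, line {lineno + 1}: mask must be length {n} "
                f"over '+'/'-'")
        mask = np.array([c == "+" for c in mask_str])

        if n <= max_length:
            records.append(
                ProteinRecord(id=rec_id, sequence=sequence, pssm=pssm,
                              coords=coords, mask=mask).validate())
    return records


def write_proteinnet(records, path, residue_order: str = AMINO_ACIDS) -> None:
    """Serialize records in the ProteinNet text dialect (ASCII).

    N and C' positions are written coincident with Cα and the id line carries
    a ``CA_ONLY`` flag; coordinates are Å × 100 (picometers) at two decimals,
    PSSM frequencies at eight decimals with a uniform information-content row.
    """
    perm = [AMINO_ACIDS.index(aa) for aa in residue_order]
    with open(path, "w") as fh:
        for rec in records:
            rec.validate()
            fh.write("[ID]\n" + rec.id + _CA_FLAG + "\n")
            fh.write("[PRIMARY]\n" + rec.sequence + "\n")
            fh.write("[EVOLUTIONARY]\n")
            for row in rec.pssm[perm]:
                fh.write("\t".join(f"{v:.8f}" for v in row) + "\n")
            info = np.zeros(rec.n)
            fh.write("\t".join(f"{v:.8f}" for v in info) + "\n")
            fh.write("[TERTIARY]\n")
            coords = np.where(np.isfinite(rec.coords), rec.coords, 0.0)
            pm = coords * _PM_PER_ANGSTROM
            for row in pm:
                trip = np.repeat(row, 3)
                fh.write("\t".join(f"{v:.2f}" for v in trip) + "\n")
            fh.write("[MASK]\n")
            fh.write("".join("+" if m else "-" for m in rec.mask) + "\n")
            fh.write("\n")


def write_ca_pdb(record_or_coords, path, sequence: str | None = None,
                 mask=None, chain_id: str = "A") -> None:
    """Write a Cα-trace PDB file (one CA atom per observed residue).

    Accepts a :class:`ProteinRecord` or a bare 3×n coordinate array.  Masked
    residues are omitted while residue numbering is preserved.
    """
    import biotite.structure as struc
    from biotite.sequence import ProteinSequence
    from biotite.structure.io.pdb import PDBFile

    if isinstance(record_or_coords, ProteinRecord):
        rec = record_or_coords
        coords, sequence, mask = rec.coords, rec.sequence, rec.mask
    else:
        coords = np.asarray(record_or_coords, float)
    n = coords.shape[1]
    if sequence is None:
        sequence = "A" * n
    mask = np.ones(n, bool) if mask is None else np.asarray(mask, bool)
    keep = np.flatnonzero(mask)
    if np.any(np.abs(coords[:, keep]) >= 10000):
        raise ValueError("coordinates overflow the PDB fixed-column format")

    atoms = struc.AtomArray(len(keep))
    atoms.coord = coords[:, keep].T
    atoms.chain_id[:] = chain_id
    atoms.res_id = keep + 1
    atoms.res_name = [ProteinSequence.convert_letter_1to3(sequence[i]) for i in keep]
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = False
    atoms.set_annotation("occupancy", np.ones(len(keep)))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)
    with open(path, "a") as fh:
        fh.write("END\n")


def write_design_outputs(pssm, sequence_onehot, record_id: str, path_prefix,
                         sample_k: int = 0, seed: int = 0) -> tuple[str, str]:
    """Write design results: a FASTA of the argmax sequence (plus optional
    PSSM samples) and a tab-separated PSSM table with 20 labeled columns.

    Returns the (fasta_path, table_path) pair.
    """
    from biotite.sequence.io.fasta import FastaFile

    pssm = np.asarray(pssm, float)
    fasta_path = f"{path_prefix}.fasta"
    table_path = f"{path_prefix}_pssm.tsv"

    fasta = FastaFile()
    fasta[record_id] = onehot_to_sequence(np.asarray(sequence_onehot))
    if sample_k:
        rng = np.random.default_rng(seed)
        for s in range(sample_k):
            seq = "".join(
                AMINO_ACIDS[rng.choice(pssm.shape[0], p=pssm[:, pos] / pssm[:, pos].sum())]
                for pos in range(pssm.shape[1]))
            fasta[f"{record_id}_sample{s}"] = seq
    fasta.write(fasta_path)

    table = pd.DataFrame(pssm.T, columns=list(AMINO_ACIDS))
    table.insert(0, "position", np.arange(1, pssm.shape[1] + 1))
    table.to_csv(table_path, sep="\t", index=False, float_format="%.6f")
    return fasta_path, table_path
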