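"""Readers and writers: FASTA, residue-table TSV, Newick, packaged fixtures.

FASTA goes through Bio.SeqIO and trees through dendropy; this module only
adds the validation and the residue-table layout the pipeline needs.  The
packaged fixtures transcribe the published residue tables for the modular
channelrhodopsins (scheme ChR2), the modular sensory-type rhodopsins (scheme
BR, numbering relative to bacteriorhodopsin), the spectral-tuning comparison
(scheme GPR) and a synthetic cyclase consensus table (scheme CYC).
"""

from __future__ import annotations

import csv
import hashlib
from importlib import resources
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    GPR_SCHEME,
    MISSING,
    SCHEMES,
    ProteinRecord,
    ReferenceScheme,
    ResidueTableRow,
    ValidationError,
    expand_entry_label,
    parse_group_label,
)

FIXTURE_SCHEMES = {
    "table1B": "ChR2",
    "table2B": "BR",
    "table3": "GPR",
    "cyclase_synthetic": "CYC",
}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are upper-cased and whitespace-stripped; duplicate ids and
    illegal residue characters raise :class:`ValidationError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        organism = rec.description[len(rec.id):].strip() or None
        records.append(ProteinRecord(id=rec.id, sequence=seq, organism=organism))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.organism or "")
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers)
# ---------------------------------------------------------------------------

def parse_newick(source: str | Path, taxon_namespace=None) -> dendropy.Tree:
    """Parse a Newick tree (path or literal string) into a dendropy Tree."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy's parse errors are a zoo
        raise ValidationError(f"malformed Newick: {exc}") from exc
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValidationError("duplicate leaf names in Newick tree")
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Residue-table TSV
# ---------------------------------------------------------------------------

def _parse_row(
    scheme: ReferenceScheme, header: list[str], values: list[str], expand: bool
) -> list[ResidueTableRow]:
    cells = dict(zip(header, values))
    entry_label = cells.get("entry") or cells.get("label")
    if entry_label is None:
        raise ValidationError("row without entry/label cell")
    role_residues: dict[str, tuple[str, int | None]] = {}
    for kp in scheme.key_positions:
        if kp.role not in cells:
            raise ValidationError(f"row {entry_label!r}: missing column {kp.role!r}")
        res = cells[kp.role].strip()
        res = MISSING if res in ("", "-") else res.upper()
        pos_text = cells.get(f"{kp.role}_pos", "").strip()
        pos = int(pos_text) if pos_text else None
        role_residues[kp.role] = (res, pos)
    is_reference = cells.get("is_reference", "0").strip() == "1"
    ids = expand_entry_label(entry_label) if expand else [entry_label]
    rows = []
    for entry_id in ids:
        row = ResidueTableRow(
            entry_id=entry_id,
            scheme_name=scheme.name,
            role_residues=dict(role_residues),
            is_reference=is_reference,
            meta={"source_label": entry_label} if len(ids) > 1 else {},
        )
        row.validate_against(scheme)
        rows.append(row)
    return rows


def read_rows(
    path: str | Path, scheme: ReferenceScheme, expand_groups: bool = True
) -> list[ResidueTableRow]:
    """Read a residue table (one row per entry, one residue+pos column pair
    per scheme role) and expand grouped entry labels."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"empty residue table {path}") from None
        rows: list[ResidueTableRow] = []
        for values in reader:
            if not any(v.strip() for v in values):
                continue
            rows.extend(_parse_row(scheme, header, values, expand_groups))
    ids = [r.entry_id for r in rows]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate entry ids in {path}: {dup}")
    return rows


def write_rows(rows: list[ResidueTableRow], scheme: ReferenceScheme, path: str | Path) -> None:
    header = ["entry", "is_reference"]
    for kp in scheme.key_positions:
        header += [kp.role, f"{kp.role}_pos"]
    with open(path, "w", newline="\n") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            out = [row.entry_id, "1" if row.is_reference else "0"]
            for kp in scheme.key_positions:
                res, pos = row.role_residues[kp.role]
                out += ["-" if res == MISSING else res, "" if pos is None else str(pos)]
            writer.writerow(out)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def fixture_path(table_name: str) -> Path:
    if table_name not in FIXTURE_SCHEMES:
        raise ValidationError(
            f"unknown fixture {table_name!r}; available: {sorted(FIXTURE_SCHEMES)}"
        )
    return Path(str(resources.files("modrhod") / "fixtures" / f"{table_name}.tsv"))


def fixture_checksums(verify: bool = True) -> dict[str, str]:
    """SHA-256 of each packaged fixture, optionally checked against the
    recorded sums shipped alongside them."""
    sums = {
        name: hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
        for name in FIXTURE_SCHEMES
    }
    if verify:
        recorded_file = resources.files("modrhod") / "fixtures" / "SHA256SUMS"
        recorded = dict(
            line.split()[::-1]
            for line in recorded_file.read_text().splitlines()
            if line.strip()
        )
        for name, digest in sums.items():
            if recorded.get(f"{name}.tsv") != digest:
                raise ValidationError(f"fixture {name} fails its checksum")
    return sums


def _load_table3(path: Path) -> list[ResidueTableRow]:
    rows: list[ResidueTableRow] = []
    by_id: dict[str, ResidueTableRow] = {}
    with open(path, newline="") as fh:
        for cells in csv.DictReader(fh, delimiter="\t"):
            for entry_id in parse_group_label(cells["label"]):
                row = ResidueTableRow(
                    entry_id=entry_id,
                    scheme_name="GPR",
                    role_residues={"spectral_tuning": (cells["residue"].strip(), None)},
                    is_reference=cells["is_reference"].strip() == "1",
                    meta={
                        "residue_name": cells["residue_name"],
                        "polarity": cells["polarity"],
                        "shift": cells["shift"],
                        "source_label": cells["label"],
                    },
                )
                if entry_id in by_id:
                    # Entry printed in two group rows: keep the later
                    # assignment, flag both residues.
                    earlier = by_id[entry_id]
                    row.meta["duplicate"] = True
                    row.meta["duplicate_residues"] = sorted(
                        {earlier.residue("spectral_tuning"), row.residue("spectral_tuning")}
                    )
                    rows.remove(earlier)
                by_id[entry_id] = row
                rows.append(row)
    return rows


def load_fixture(table_name: str) -> tuple[ReferenceScheme, list[ResidueTableRow]]:
    """Load a packaged residue table, expanding grouped entry labels.

    Reference proteins (e.g. the seven non-modular rhodopsins of the BR
    table) carry ``is_reference=True`` and are excluded from modular counts
    downstream.
    """
    path = fixture_path(table_name)
    scheme = SCHEMES[FIXTURE_SCHEMES[table_name]]
    if table_name == "table3":
        return GPR_SCHEME, _load_table3(path)
    return scheme, read_rows(path, scheme, expand_groups=True)


def modular_rows(rows: list[ResidueTableRow]) -> list[ResidueTableRow]:
    return [r for r in rows if not r.is_reference]
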