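"""Reference-position projection by pairwise global alignment.

The published residue tables number every key residue "with respect to" a
reference rhodopsin (BR or ChR2).  This module reproduces that numbering
transfer: each query is globally aligned to the reference scaffold
(Needleman–Wunsch, BLOSUM62, affine gaps) and the scheme's key positions are
projected through the alignment onto query coordinates, yielding a residue
fingerprint per query.  Pairwise projection against the scaffold replaces
the multiple alignment used in the original analysis: it needs no external
MSA tool and preserves the position-numbering semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .records import (
    ALLOWED_ALPHABET,
    GAP,
    ProteinRecord,
    ReferenceScheme,
    ResidueTableRow,
    ValidationError,
)
from . import topology as _topology

logger = logging.getLogger(__name__)

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two equal-length gapped strings plus its score."""

    reference: str
    query: str
    score: float

    def __post_init__(self) -> None:
        if len(self.reference) != len(self.query):
            raise ValidationError("aligned strings differ in length")
        if any(a == GAP and b == GAP for a, b in zip(self.reference, self.query)):
            raise ValidationError("gap/gap column in alignment")

    def columns(self):
        return zip(self.reference, self.query)


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValidationError(f"{name} sequence is empty")
    bad = set(seq) - ALLOWED_ALPHABET
    if bad:
        raise ValidationError(f"{name} sequence has invalid residues {sorted(bad)}")


def global_align(
    reference_seq: str,
    query_seq: str,
    substitution_table: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment under BLOSUM62 with affine gap penalties.

    ``gap_open``/``gap_extend`` are positive penalties; a gap of length L
    costs ``gap_open + (L-1)*gap_extend``.  Among co-optimal alignments a
    fixed traceback order is used, so the result is deterministic.
    """
    _check_sequence(reference_seq, "reference")
    _check_sequence(query_seq, "query")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_table)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignment = aligner.align(reference_seq, query_seq)[0]
    return PairwiseAlignment(
        reference=alignment[0], query=alignment[1], score=alignment.score
    )


def map_positions(alignment: PairwiseAlignment, scheme: ReferenceScheme) -> ResidueTableRow:
    """Project the scheme's key positions through an alignment onto the query.

    For each key position the alignment column holding that reference residue
    is located; if the query side of the column is a gap the role maps to
    :data:`GAP` with no position, otherwise the query's 1-based coordinate and
    residue are recorded.
    """
    ref_len = sum(1 for c in alignment.reference if c != GAP)
    for kp in scheme.key_positions:
        if kp.position > ref_len:
            raise ValidationError(
                f"scheme {scheme.name} position {kp.position} exceeds reference length {ref_len}"
            )
    wanted = {kp.position: kp.role for kp in scheme.key_positions}
    role_residues: dict[str, tuple[str, int | None]] = {}
    ref_pos = 0
    query_pos = 0
    for ref_ch, q_ch in alignment.columns():
        if ref_ch != GAP:
            ref_pos += 1
        if q_ch != GAP:
            query_pos += 1
        if ref_ch != GAP and ref_pos in wanted:
            role = wanted[ref_pos]
            if q_ch == GAP:
                role_residues[role] = (GAP, None)
            else:
                role_residues[role] = (q_ch, query_pos)
    return ResidueTableRow(
        entry_id="", scheme_name=scheme.name, role_residues=role_residues
    )


def fingerprint(
    record: ProteinRecord,
    scheme: ReferenceScheme,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ResidueTableRow:
    """Align one record to the scheme scaffold and read off its fingerprint."""
    if scheme.scaffold is None:
        raise ValidationError(f"scheme {scheme.name} carries no scaffold sequence")
    aln = global_align(scheme.scaffold, record.sequence, gap_open=gap_open, gap_extend=gap_extend)
    row = map_positions(aln, scheme)
    row.entry_id = record.id
    return row


def extract_fingerprints(
    records: list[ProteinRecord],
    scheme: ReferenceScheme,
    validate: bool = True,
    force: bool = False,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    topology_params: dict | None = None,
) -> tuple[list[ResidueTableRow], list[tuple[str, str]]]:
    """Fingerprint a batch of records against one scheme.

    Records failing the seven-helix/retinal-lysine validation are skipped
    (unless ``force``), and per-record failures do not abort the batch; the
    second return value lists ``(record_id, reason)`` for every skip.
    """
    rows: list[ResidueTableRow] = []
    failures: list[tuple[str, str]] = []
    for record in records:
        try:
            if validate and not force:
                _, ok, reasons = _topology.detect(record, **(topology_params or {}))
                if not ok:
                    raise ValidationError("; ".join(reasons))
            rows.append(fingerprint(record, scheme, gap_open, gap_extend))
        except ValidationError as exc:
            logger.warning("skipping %s: %s", record.id, exc)
            failures.append((record.id, str(exc)))
    return rows, failures
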