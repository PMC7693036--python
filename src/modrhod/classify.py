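"""Rule-based functional, spectral and cyclase classification.

The rules encode the residue requirements of the rhodopsin photocycle:

* **Channel competence** (ChR2 numbering): proton acceptor Asp/Glu-253,
  proton donor Asp-156, DC-gate Cys-128 (hydrogen-bonded to the donor),
  acceptor-stabilising Arg-120 and Schiff-base Lys-257.
* **Pump competence** (BR numbering): proton acceptor Asp/Glu-85, proton
  donor Asp-96, counterion Asp-212 and Schiff-base Lys-216.  Thr-89/Thr-90
  and the proton-release pair Glu-194/Glu-204 are recorded as evidence but
  do not gate the call: the one genuinely pump-competent modular rhodopsin
  (AsRh4) carries Gly at 194, so gating on proton release would wrongly
  exclude it.
* **Spectral tuning** (proteorhodopsin numbering): the polarity of the
  residue at the 105-equivalent site — nonpolar predicts green absorbance,
  polar-uncharged predicts blue, charged residues are unassigned.
* **Cyclase activity**: class-III nucleotidyl cyclase consensus — two
  metal-binding aspartates plus canonical substrate-binding and
  transition-state-stabilising residues; a row missing them is a degenerate
  (inactive) cyclase.

An entry whose Schiff-base attachment site is not lysine cannot form the
retinylidene chromophore at all and is called NON_RETINYLIDENE regardless of
the other rules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .records import (
    AMINO_ACIDS,
    BR_SCHEME,
    CHR2_SCHEME,
    CYC_SCHEME,
    GAP,
    MISSING,
    ReferenceScheme,
    ResidueTableRow,
    ValidationError,
)


class FunctionalClass(str, enum.Enum):
    CHANNEL_COMPETENT = "CHANNEL_COMPETENT"
    PUMP_COMPETENT = "PUMP_COMPETENT"
    SENSORY_ATYPICAL = "SENSORY_ATYPICAL"
    NON_RETINYLIDENE = "NON_RETINYLIDENE"


class SpectralClass(str, enum.Enum):
    GREEN = "GREEN"
    BLUE = "BLUE"
    UNKNOWN = "UNKNOWN"
    UNSCORED = "UNSCORED"


class CyclaseClass(str, enum.Enum):
    ACTIVE = "ACTIVE"
    DEGENERATE = "DEGENERATE"
    NOT_APPLICABLE = "NOT_APPLICABLE"


#: Polarity partition for the spectral-tuning rule (config-overridable).
NONPOLAR = frozenset("AVLIMFWPGC")
POLAR_UNCHARGED = frozenset("STNQY")
CHARGED = frozenset("DEHKR")


@dataclass
class AnnotationCall:
    """Combined classification of one entry with per-rule evidence."""

    entry_id: str
    functional_class: FunctionalClass | None = None
    spectral_class: SpectralClass | None = None
    cyclase_class: CyclaseClass | None = None
    evidence: dict[str, bool] = field(default_factory=dict)
    is_reference: bool = False

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "functional_class": self.functional_class.value if self.functional_class else None,
            "spectral_class": self.spectral_class.value if self.spectral_class else None,
            "cyclase_class": self.cyclase_class.value if self.cyclase_class else None,
            "evidence": dict(sorted(self.evidence.items())),
            "is_reference": self.is_reference,
        }


@dataclass(frozen=True)
class ConservationCount:
    """How many modular entries carry a residue from a query set at one
    scheme position.  MISSING cells never count toward the numerator but do
    stay in the denominator."""

    position: int
    residue_set: frozenset[str]
    count: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.count <= self.denominator:
            raise ValidationError("count outside [0, denominator]")


def _require_scheme(row: ResidueTableRow, scheme: ReferenceScheme) -> None:
    if row.scheme_name != scheme.name:
        raise ValidationError(
            f"row {row.entry_id!r} follows scheme {row.scheme_name!r}, expected {scheme.name!r}"
        )
    row.validate_against(scheme)


def _rule(row: ResidueTableRow, role: str, allowed: frozenset[str] | set[str]) -> bool:
    return row.residue(role) in allowed


def classify_channel(row: ResidueTableRow) -> AnnotationCall:
    """Channel-competence call for a ChR2-scheme row."""
    _require_scheme(row, CHR2_SCHEME)
    evidence = {
        "proton_acceptor": _rule(row, "proton_acceptor", {"D", "E"}),
        "proton_donor": _rule(row, "proton_donor", {"D"}),
        "dc_gate": _rule(row, "dc_gate", {"C"}),
        "stabilizer": _rule(row, "stabilizer", {"R"}),
        "retinal_attachment": _rule(row, "retinal_attachment", {"K"}),
    }
    if not evidence["retinal_attachment"]:
        cls = FunctionalClass.NON_RETINYLIDENE
    elif all(evidence.values()):
        cls = FunctionalClass.CHANNEL_COMPETENT
    else:
        cls = FunctionalClass.SENSORY_ATYPICAL
    return AnnotationCall(
        entry_id=row.entry_id,
        functional_class=cls,
        evidence=evidence,
        is_reference=row.is_reference,
    )


def classify_pump(row: ResidueTableRow) -> AnnotationCall:
    """Pump-competence call for a BR-scheme row."""
    _require_scheme(row, BR_SCHEME)
    gating = {
        "proton_acceptor": _rule(row, "proton_acceptor", {"D", "E"}),
        "proton_donor": _rule(row, "proton_donor", {"D"}),
        "counterion": _rule(row, "counterion", {"D"}),
        "retinal_attachment": _rule(row, "retinal_attachment", {"K"}),
    }
    evidence = dict(gating)
    evidence["acceptor_stabilizer"] = _rule(row, "acceptor_stabilizer", {"S", "T"})
    evidence["retinal_pocket"] = _rule(row, "retinal_pocket", {"T"})
    evidence["proton_release_194"] = _rule(row, "proton_release_194", {"D", "E"})
    evidence["proton_release_204"] = _rule(row, "proton_release_204", {"D", "E"})
    if not gating["retinal_attachment"]:
        cls = FunctionalClass.NON_RETINYLIDENE
    elif all(gating.values()):
        cls = FunctionalClass.PUMP_COMPETENT
    else:
        cls = FunctionalClass.SENSORY_ATYPICAL
    return AnnotationCall(
        entry_id=row.entry_id,
        functional_class=cls,
        evidence=evidence,
        is_reference=row.is_reference,
    )


def classify_spectral(residue: str) -> SpectralClass:
    """Spectral-tuning call from the proteorhodopsin-105-equivalent residue."""
    if residue in (GAP, MISSING):
        return SpectralClass.UNSCORED
    if residue == "X":
        return SpectralClass.UNSCORED
    if residue in NONPOLAR:
        return SpectralClass.GREEN
    if residue in POLAR_UNCHARGED:
        return SpectralClass.BLUE
    if residue in CHARGED:
        return SpectralClass.UNKNOWN
    raise ValidationError(f"invalid residue code {residue!r}")


def classify_cyclase(row: ResidueTableRow | None) -> CyclaseClass:
    """Cyclase-activity call for a CYC-scheme row (None = no cyclase domain)."""
    if row is None:
        return CyclaseClass.NOT_APPLICABLE
    _require_scheme(row, CYC_SCHEME)
    ok = all(
        row.residue(kp.role) in kp.expected for kp in CYC_SCHEME.key_positions
    )
    return CyclaseClass.ACTIVE if ok else CyclaseClass.DEGENERATE


def tabulate_conservation(
    rows: list[ResidueTableRow],
    position: int,
    residue_set: set[str] | frozenset[str] | str,
    scheme: ReferenceScheme = BR_SCHEME,
) -> ConservationCount:
    """Count modular entries with a residue from ``residue_set`` at a scheme
    position.  Reference rows are excluded entirely; modular rows with a
    MISSING cell stay in the denominator but can never match."""
    role = scheme.role_at(position)
    residues = frozenset(residue_set)
    modular = [r for r in rows if not r.is_reference]
    count = sum(1 for r in modular if r.residue(role) in residues)
    return ConservationCount(
        position=position,
        residue_set=residues,
        count=count,
        denominator=len(modular),
    )


_CLASSIFIERS = {"ChR2": classify_channel, "BR": classify_pump}


def annotate_rows(
    rows: list[ResidueTableRow],
    scheme: ReferenceScheme,
    spectral_residues: dict[str, str] | None = None,
    cyclase_rows: dict[str, ResidueTableRow] | None = None,
) -> list[AnnotationCall]:
    """Run the rule engine over pre-extracted rows.

    ``spectral_residues`` (entry id → 105-equivalent residue) and
    ``cyclase_rows`` (entry id → CYC-scheme row) optionally add spectral and
    cyclase calls; entries absent from ``cyclase_rows`` are NOT_APPLICABLE
    when the mapping is provided.
    """
    if scheme.name not in _CLASSIFIERS:
        raise ValidationError(f"no functional classifier for scheme {scheme.name!r}")
    classifier = _CLASSIFIERS[scheme.name]
    calls = []
    for row in rows:
        call = classifier(row)
        if spectral_residues is not None:
            residue = spectral_residues.get(row.entry_id)
            call.spectral_class = (
                classify_spectral(residue) if residue is not None else SpectralClass.UNSCORED
            )
        if cyclase_rows is not None:
            call.cyclase_class = classify_cyclase(cyclase_rows.get(row.entry_id))
        calls.append(call)
    return calls


def annotate_records(
    records,
    scheme: ReferenceScheme,
    force: bool = False,
    **refmap_params,
) -> tuple[list[AnnotationCall], list[tuple[str, str]]]:
    """Full pipeline: topology validation → fingerprint extraction → rules."""
    from . import refmap

    rows, failures = refmap.extract_fingerprints(
        records, scheme, force=force, **refmap_params
    )
    return annotate_rows(rows, scheme), failures
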