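"""Domain types shared by all pipeline stages.

The pipeline annotates microbial (type I) rhodopsins: seven-transmembrane,
retinal-binding photoreceptors.  Residue positions throughout are 1-based and
expressed in the numbering of a *reference scheme* — a well-characterised
rhodopsin (bacteriorhodopsin, channelrhodopsin-2, green proteorhodopsin) or a
canonical cyclase — whose functionally assigned key positions are projected
onto query sequences by global alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: 20 canonical amino acids plus X (unknown).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: Sentinel for an alignment column where the query carries a gap.
GAP = "-"
#: Sentinel for a table cell the source table leaves blank ("-" in print).
MISSING = "."


class ValidationError(ValueError):
    """Raised when a record or table violates a structural invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein sequence."""

    id: str
    sequence: str
    organism: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for offset, ch in enumerate(self.sequence):
            if ch not in ALLOWED_ALPHABET:
                raise ValidationError(
                    f"record {self.id!r}: illegal character {ch!r} at offset {offset}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class KeyPosition:
    """A role-annotated position in reference numbering.

    ``expected`` is the residue set regarded as canonical for the role; an
    empty set means the role carries no expectation (it is read out, not
    checked), as for the spectral-tuning site.
    """

    role: str
    position: int
    expected: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"role {self.role!r}: position must be 1-based")


@dataclass(frozen=True)
class ReferenceScheme:
    """A named reference protein with its key positions.

    ``scaffold`` is the reference amino-acid sequence used as the alignment
    target; built-in schemes ship without one (the user supplies the real
    reference FASTA; the synthetic module builds toy scaffolds for tests).
    """

    name: str
    key_positions: tuple[KeyPosition, ...]
    scaffold: str | None = None

    def __post_init__(self) -> None:
        roles = [kp.role for kp in self.key_positions]
        if len(set(roles)) != len(roles):
            raise ValidationError(f"scheme {self.name}: duplicate roles")
        positions = [kp.position for kp in self.key_positions]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValidationError(f"scheme {self.name}: positions not strictly increasing")
        if self.scaffold is not None and positions and positions[-1] > len(self.scaffold):
            raise ValidationError(
                f"scheme {self.name}: key position {positions[-1]} exceeds scaffold length"
            )

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(kp.role for kp in self.key_positions)

    def role(self, name: str) -> KeyPosition:
        for kp in self.key_positions:
            if kp.role == name:
                return kp
        raise KeyError(f"scheme {self.name} has no role {name!r}")

    def position_of(self, role: str) -> int:
        return self.role(role).position

    def role_at(self, position: int) -> str:
        for kp in self.key_positions:
            if kp.position == position:
                return kp.role
        raise KeyError(f"scheme {self.name} has no key position {position}")

    def with_scaffold(self, scaffold: str, positions: dict[str, int]) -> "ReferenceScheme":
        """Re-number the scheme onto a new scaffold (used by toy scaffolds)."""
        kps = tuple(
            KeyPosition(kp.role, positions[kp.role], kp.expected)
            for kp in sorted(self.key_positions, key=lambda k: positions[k.role])
        )
        return ReferenceScheme(self.name, kps, scaffold)


@dataclass
class ResidueTableRow:
    """Role → observed residue (and query position) for one entry.

    This is both the parsed form of the packaged residue tables and the
    output of alignment-based fingerprint extraction.  ``residue`` is a
    1-letter code, :data:`GAP` (query gapped at the reference column) or
    :data:`MISSING` (cell absent from the source table).
    """

    entry_id: str
    scheme_name: str
    role_residues: dict[str, tuple[str, int | None]]
    is_reference: bool = False
    meta: dict = field(default_factory=dict)

    def residue(self, role: str) -> str:
        return self.role_residues[role][0]

    def position(self, role: str) -> int | None:
        return self.role_residues[role][1]

    def validate_against(self, scheme: ReferenceScheme) -> None:
        missing = set(scheme.roles) - set(self.role_residues)
        if missing:
            raise ValidationError(
                f"row {self.entry_id!r}: roles missing for scheme {scheme.name}: {sorted(missing)}"
            )
        for role, (res, _pos) in self.role_residues.items():
            if res not in ALLOWED_ALPHABET and res not in (GAP, MISSING):
                raise ValidationError(
                    f"row {self.entry_id!r}: invalid residue {res!r} for role {role}"
                )


# ---------------------------------------------------------------------------
# Built-in reference schemes
# ---------------------------------------------------------------------------

def _kp(role: str, pos: int, expected: str = "") -> KeyPosition:
    return KeyPosition(role, pos, frozenset(expected))


#: Bacteriorhodopsin numbering; pump/sensory discrimination.
BR_SCHEME = ReferenceScheme(
    "BR",
    (
        _kp("proton_acceptor", 85, "DE"),
        _kp("acceptor_stabilizer", 89, "ST"),
        _kp("retinal_pocket", 90, "T"),
        _kp("proton_donor", 96, "D"),
        _kp("proton_release_194", 194, "DE"),
        _kp("proton_release_204", 204, "DE"),
        _kp("counterion", 212, "D"),
        _kp("retinal_attachment", 216, "K"),
    ),
)

#: Channelrhodopsin-2 numbering; channel-competence discrimination.
CHR2_SCHEME = ReferenceScheme(
    "ChR2",
    (
        _kp("stabilizer", 120, "R"),
        _kp("dc_gate", 128, "C"),
        _kp("proton_donor", 156, "D"),
        _kp("proton_acceptor", 253, "DE"),
        _kp("retinal_attachment", 257, "K"),
    ),
)

#: Green proteorhodopsin numbering; single spectral-tuning site.
GPR_SCHEME = ReferenceScheme(
    "GPR",
    (_kp("spectral_tuning", 105),),
)

#: Class-III nucleotidyl cyclase consensus, positions ordinal relative to a
#: user- or test-supplied canonical cyclase reference row.
CYC_SCHEME = ReferenceScheme(
    "CYC",
    (
        _kp("metal_binding_1", 1, "D"),
        _kp("metal_binding_2", 2, "D"),
        _kp("substrate_binding", 3, "EK"),
        _kp("transition_state", 4, "NR"),
    ),
)

SCHEMES: dict[str, ReferenceScheme] = {
    s.name: s for s in (BR_SCHEME, CHR2_SCHEME, GPR_SCHEME, CYC_SCHEME)
}


# ---------------------------------------------------------------------------
# Grouped entry labels
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(?P<prefix>.*?[A-Za-z])(?P<a>\d+)\s*[-/]\s*(?P<b>\d+)$")


def expand_entry_label(label: str) -> list[str]:
    """Expand a grouped entry label into individual entry ids.

    A label whose tail is ``<n>-<m>`` or ``<n>/<m>`` after an alphabetic
    prefix denotes several proteins sharing one residue row; it expands to one
    id per numeral of the inclusive range (``Cop9-10`` → ``Cop9``, ``Cop10``;
    ``GtRh2/3`` → ``GtRh2``, ``GtRh3``).  Plain labels pass through.
    """
    m = _RANGE_RE.match(label.strip())
    if not m:
        return [label.strip()]
    prefix, a, b = m.group("prefix"), int(m.group("a")), int(m.group("b"))
    if b < a:
        raise ValidationError(f"label {label!r}: descending numeral range")
    return [f"{prefix}{i}" for i in range(a, b + 1)]


def parse_group_label(label: str) -> list[str]:
    """Expand a free-form group label listing several entries.

    Handles comma- and ``and``-separated lists, numeral ranges, and bare
    numeral tokens that inherit the previous token's alphabetic prefix
    (``GtRh2,3`` → ``GtRh2``, ``GtRh3``).
    """
    tokens: list[str] = []
    for part in re.split(r",|\band\b", label):
        part = part.strip()
        if part:
            tokens.append(part)
    out: list[str] = []
    prev_prefix = ""
    for tok in tokens:
        if tok.isdigit():
            if not prev_prefix:
                raise ValidationError(f"label {label!r}: bare numeral with no prefix")
            out.append(f"{prev_prefix}{tok}")
            continue
        expanded = expand_entry_label(tok)
        m = re.match(r"^(.*?[A-Za-z])\d", expanded[0])
        prev_prefix = m.group(1) if m else ""
        out.extend(expanded)
    return out
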