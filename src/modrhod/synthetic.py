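"""Synthetic rhodopsin-like sequences with known ground truth.

The generators build what the pipeline assumes real data looks like, with
the truth planted and recorded so every stage can be tested without any
download: seven hydrophobic helical stretches separated by hydrophilic
loops (clean Kyte–Doolittle segmentation by construction), scheme key
positions placed at fixed helix-interior offsets (≥ 3 residues from helix
edges so window smoothing cannot detach them), specified residues planted
at those positions, and sequence families evolved along a known tree for
the phylogeny tests.

These toy sequences deliberately lack most features of real rhodopsins —
no indels, no composition bias, no correlated substitutions — so passing
tests demonstrate correctness of the machinery, not performance on real
proteins.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import io as _io
from .records import (
    AMINO_ACIDS,
    SCHEMES,
    ProteinRecord,
    ReferenceScheme,
    ResidueTableRow,
    ValidationError,
)

#: Helix alphabet: strongly hydrophobic, guaranteeing scores above the
#: segmentation threshold; loop alphabet: hydrophilic.
HYDROPHOBIC = "AVLIFM"
HYDROPHILIC = "DENQKRSTGH"

# The window-19 hydropathy mean leaves a super-threshold run of roughly
# helix_len - 10, so helices carry a margin over the detector's min_len
# even with one or two planted polar key residues inside them.
DEFAULT_HELIX_LEN = 30
DEFAULT_LOOP_LEN = 8
#: Key-position slots inside a helix, as offsets from the helix start.
#: Deep enough that window smoothing (which erodes a helix's detected
#: interval by a few residues on each side) cannot detach a key residue
#: from its helix.
_SLOT_MARGIN = 7


@dataclass(frozen=True)
class SyntheticScaffold:
    """A generated reference scaffold with its renumbered scheme."""

    record: ProteinRecord
    scheme: ReferenceScheme
    helices: tuple[tuple[int, int], ...]
    key_coords: dict[str, int]


@dataclass(frozen=True)
class FingerprintSpec:
    """What to plant into a scaffold-derived variant."""

    scheme_name: str
    role_residues: dict[str, str]
    rate: float = 0.0
    seed: int = 0
    entry_id: str = "variant"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 0.2:
            raise ValidationError("background mutation rate must be in [0, 0.2]")
        for role, res in self.role_residues.items():
            if res not in AMINO_ACIDS:
                raise ValidationError(f"role {role}: invalid residue {res!r}")


def _slot_plan(n_roles: int, n_helices: int, helix_len: int) -> list[tuple[int, int]]:
    """Assign roles to (helix index, in-helix offset) slots.

    The last role always sits at the centre of the last helix (the
    retinal-attachment site must fall inside the detected seventh helix);
    the rest are spread round-robin over the earlier helices, at most two
    per helix, the two slots far apart.
    """
    slots = [(h, _SLOT_MARGIN) for h in range(n_helices - 1)]
    slots += [(h, helix_len - _SLOT_MARGIN - 1) for h in range(n_helices - 1)]
    if n_roles - 1 > len(slots):
        raise ValidationError("too many roles for this scaffold geometry")
    plan = slots[: n_roles - 1]
    plan.append((n_helices - 1, helix_len // 2))
    return plan


def make_scaffold(
    scheme: ReferenceScheme | str,
    n_helices: int = 7,
    helix_len: int = DEFAULT_HELIX_LEN,
    loop_len: int = DEFAULT_LOOP_LEN,
    seed: int = 0,
) -> SyntheticScaffold:
    """Build a rhodopsin-like scaffold carrying the scheme's roles.

    The scaffold alternates hydrophilic loops with hydrophobic helices; each
    scheme role is planted at a fixed helix-interior coordinate with its
    canonical residue, and the scheme is renumbered onto those coordinates.
    Deterministic per seed.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    if min(n_helices, helix_len, loop_len) < 1:
        raise ValidationError("scaffold geometry parameters must be positive")
    rng = np.random.default_rng(seed)
    helices: list[tuple[int, int]] = []
    seq: list[str] = list(rng.choice(list(HYDROPHILIC), size=loop_len))
    for _ in range(n_helices):
        start = len(seq) + 1
        seq.extend(rng.choice(list(HYDROPHOBIC), size=helix_len))
        helices.append((start, len(seq)))
        seq.extend(rng.choice(list(HYDROPHILIC), size=loop_len))

    plan = _slot_plan(len(scheme.key_positions), n_helices, helix_len)
    key_coords: dict[str, int] = {}
    for kp, (helix_idx, offset) in zip(scheme.key_positions, plan):
        pos = helices[helix_idx][0] + offset
        canonical = sorted(kp.expected)[0] if kp.expected else "L"
        seq[pos - 1] = canonical
        key_coords[kp.role] = pos

    sequence = "".join(seq)
    renumbered = scheme.with_scaffold(sequence, key_coords)
    record = ProteinRecord(id=f"{scheme.name}_scaffold", sequence=sequence)
    return SyntheticScaffold(
        record=record,
        scheme=renumbered,
        helices=tuple(helices),
        key_coords=key_coords,
    )


def make_variant(
    scaffold: SyntheticScaffold, spec: FingerprintSpec
) -> tuple[ProteinRecord, ResidueTableRow]:
    """Derive a variant: plant the spec's residues at the scaffold's key
    coordinates, apply hydrophobicity-preserving background substitutions
    elsewhere at the spec's rate, and return the record together with its
    ground-truth fingerprint row."""
    if spec.scheme_name != scaffold.scheme.name:
        raise ValidationError(
            f"spec scheme {spec.scheme_name!r} != scaffold scheme {scaffold.scheme.name!r}"
        )
    unknown = set(spec.role_residues) - set(scaffold.scheme.roles)
    if unknown:
        raise ValidationError(f"spec names unknown roles {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    seq = list(scaffold.record.sequence)
    key_positions = set(scaffold.key_coords.values())
    in_helix = np.zeros(len(seq), dtype=bool)
    for start, end in scaffold.helices:
        in_helix[start - 1:end] = True
    if spec.rate > 0:
        hits = rng.random(len(seq)) < spec.rate
        for i in np.flatnonzero(hits):
            if i + 1 in key_positions:
                continue
            pool = HYDROPHOBIC if in_helix[i] else HYDROPHILIC
            seq[i] = pool[rng.integers(len(pool))]
    truth: dict[str, tuple[str, int | None]] = {}
    for kp in scaffold.scheme.key_positions:
        pos = scaffold.key_coords[kp.role]
        residue = spec.role_residues.get(kp.role, scaffold.record.sequence[pos - 1])
        seq[pos - 1] = residue
        truth[kp.role] = (residue, pos)
    record = ProteinRecord(id=spec.entry_id, sequence="".join(seq))
    row = ResidueTableRow(
        entry_id=spec.entry_id, scheme_name=scaffold.scheme.name, role_residues=truth
    )
    return record, row


def evolve_family(
    tree: dendropy.Tree,
    scaffold: ProteinRecord,
    rate_per_branch: float = 1.0,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Evolve the scaffold along a tree under a uniform replacement model.

    Each site substitutes independently on each branch with probability
    ``rate_per_branch × branch length`` (capped at 0.95), the replacement
    drawn uniformly from the other 19 residues.  Leaf sequences are returned
    in leaf-iteration order; deterministic per seed.
    """
    if rate_per_branch < 0:
        raise ValidationError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    seqs: dict[int, str] = {id(tree.seed_node): scaffold.sequence}
    leaves: list[ProteinRecord] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        length = node.edge.length or 0.0
        p = min(rate_per_branch * length, 0.95)
        seq = list(parent_seq)
        if p > 0:
            hits = rng.random(len(seq)) < p
            for i in np.flatnonzero(hits):
                choices = AMINO_ACIDS.replace(seq[i], "")
                seq[i] = choices[rng.integers(len(choices))]
        child_seq = "".join(seq)
        seqs[id(node)] = child_seq
        if node.is_leaf():
            if node.taxon is None:
                raise ValidationError("tree leaves must be named")
            leaves.append(ProteinRecord(id=node.taxon.label, sequence=child_seq))
    return leaves


def random_tree(
    n_taxa: int,
    seed: int,
    branch_range: tuple[float, float] = (0.1, 1.0),
    taxon_namespace=None,
) -> dendropy.Tree:
    """A random unrooted binary topology with uniform branch lengths,
    used for additivity and recovery experiments."""
    if n_taxa < 3:
        raise ValidationError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(label))
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    center = dendropy.Node()
    for node in nodes:
        center.add_child(node)
    lo, hi = branch_range
    tree.seed_node = center
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.uniform(lo, hi))
    tree.is_rooted = False
    return tree


#: Named variant presets for the CLI: planted residues in published-table
#: order for a BR- or ChR2-style fingerprint.
PRESETS: dict[str, FingerprintSpec] = {
    "asrh4-like": FingerprintSpec(
        "BR",
        {
            "proton_acceptor": "D", "acceptor_stabilizer": "T",
            "retinal_pocket": "T", "proton_donor": "D",
            "proton_release_194": "G", "proton_release_204": "E",
            "counterion": "D", "retinal_attachment": "K",
        },
        entry_id="AsRh4_like",
    ),
    "cop6-like": FingerprintSpec(
        "BR",
        {
            "proton_acceptor": "Q", "acceptor_stabilizer": "T",
            "retinal_pocket": "T", "proton_donor": "I",
            "proton_release_194": "V", "proton_release_204": "G",
            "counterion": "N", "retinal_attachment": "K",
        },
        entry_id="Cop6_like",
    ),
    "knrh3-like": FingerprintSpec(
        "ChR2",
        {
            "stabilizer": "R", "dc_gate": "C", "proton_donor": "D",
            "proton_acceptor": "D", "retinal_attachment": "K",
        },
        entry_id="KnRh3_like",
    ),
}


def table_fixtures(verify: bool = True) -> dict[str, str]:
    """Paths of the packaged residue-table fixtures, checksum-verified."""
    _io.fixture_checksums(verify=verify)
    return {name: str(_io.fixture_path(name)) for name in _io.FIXTURE_SCHEMES}
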