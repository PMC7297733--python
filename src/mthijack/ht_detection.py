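"""Horizontal-transfer event detection and characterisation.

A horizontal transfer (HT) event is inferred when the mitochondrial
haplotype assignment of a group of tumours is discordant with their
position on the clonal nuclear tree.  Tumours sharing a donor haplotype are
partitioned into maximal subsets that each form the complete tip set of a
nuclear-tree clade containing only members of that subset; each such
subset is one HT event.  The haplotype that the incoming mtDNA displaced is
reconstructed by parsimony at the parent of the event clade, treating the
event's own tips as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

from .phylo_core import mpr_reconstruction, sankoff_mpr
from .variant_store import Variant, VariantTable


@dataclass
class HTEvent:
    """One horizontal-transfer event on the nuclear tree."""

    event_id: str
    donor_haplotype: str
    members: tuple[str, ...]
    replaced_haplotype: str = "Unknown"
    heteroplasmy: dict[str, float] = field(default_factory=dict)
    location: str = "ambiguous"
    somatic_counts: dict[str, int] = field(default_factory=dict)
    fixed_unknown: frozenset[Variant] = frozenset()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an HT event must have members")
        for m in self.members:
            self.heteroplasmy.setdefault(m, 1.0)
        for m, f in self.heteroplasmy.items():
            if not 0 < f <= 1:
                raise ValueError(f"heteroplasmy fraction {f} outside (0, 1]")

    @property
    def n_tumours(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HeteroplasmyCall:
    tumour_id: str
    fractions: tuple[tuple[str, float], ...]
    host_haplotype: str
    is_heteroplasmic: bool


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_ht_events(nuclear_tree: dendropy.Tree,
                     tumour_haplotypes: Mapping[str, str]) -> list[HTEvent]:
    """Group tumours into transfer events by nuclear/mtDNA discordance.

    A canonical most-parsimonious haplotype labelling of the nuclear tree
    is computed (one state per node, deterministic tie-breaks); every
    change-free connected region of the tree that contains tumour tips of
    its state is one HT event.  This equals the "maximal same-haplotype
    clade" grouping whenever events form clean, non-nested clades, and
    keeps a background lineage as a single event when later transfers nest
    inside it (paraphyly), matching the parsimony count: on clean cohorts
    the number of events is the minimum change count + 1.  Events are
    numbered HT1, HT2, ... in tree preorder of their region roots.
    """
    tips = {leaf.taxon.label for leaf in nuclear_tree.leaf_node_iter()
            if leaf.taxon}
    missing = set(tumour_haplotypes) - tips
    if missing:
        raise ValueError(f"tumours absent from tree: {sorted(missing)}")
    unlabelled = tips - set(tumour_haplotypes)
    if unlabelled:
        raise ValueError(f"tips without haplotype label: {sorted(unlabelled)}")

    reconstruction = mpr_reconstruction(nuclear_tree, tumour_haplotypes)
    # each tip climbs to the highest ancestor reachable without a state
    # change; tips sharing that region root belong to one event
    region_root: dict[str, dendropy.Node] = {}
    for leaf in nuclear_tree.leaf_node_iter():
        node = leaf
        while node.parent_node is not None and \
                reconstruction[node.parent_node] == reconstruction[leaf]:
            node = node.parent_node
        region_root[leaf.taxon.label] = node

    groups: dict[int, list[str]] = {}
    roots: dict[int, dendropy.Node] = {}
    for label, root in region_root.items():
        groups.setdefault(id(root), []).append(label)
        roots[id(root)] = root

    preorder_rank = {id(n): i
                     for i, n in enumerate(nuclear_tree.preorder_node_iter())}
    events: list[HTEvent] = []
    for key in sorted(groups, key=lambda k: preorder_rank[k]):
        members = tuple(sorted(groups[key]))
        events.append(HTEvent(
            event_id=f"HT{len(events) + 1}",
            donor_haplotype=tumour_haplotypes[members[0]],
            members=members))
    return events


def infer_replaced_haplotype(event: HTEvent, nuclear_tree: dendropy.Tree,
                             tumour_haplotypes: Mapping[str, str]) -> str:
    """Parsimony-reconstructed incumbent haplotype above the event.

    Every tip descending from the event's region root (the event's own
    members and any later transfers nested inside the region) is treated as
    missing data, and the most-parsimonious state set at the parent of the
    region root is computed.  A singleton set is the replaced haplotype;
    the root of the tree or an ambiguous set yields "Unknown".
    """
    taxa = [nuclear_tree.taxon_namespace.get_taxon(m) for m in event.members]
    mrca = nuclear_tree.mrca(taxa=taxa) if len(taxa) > 1 else \
        nuclear_tree.find_node_with_taxon_label(event.members[0])
    if mrca is None or mrca.parent_node is None:
        return "Unknown"
    masked = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    states = {label: (None if label in masked else hap)
              for label, hap in tumour_haplotypes.items()}
    if all(s is None for s in states.values()):
        return "Unknown"
    mpr, _ = sankoff_mpr(nuclear_tree, states)
    parent_set = mpr[mrca.parent_node]
    if len(parent_set) == 1:
        return next(iter(parent_set))
    return "Unknown"


# ---------------------------------------------------------------------------
# Heteroplasmy
# ---------------------------------------------------------------------------

def call_heteroplasmy(haplotype_fractions: Mapping[str, float],
                      host_haplotype: str, threshold: float = 0.10,
                      tumour_id: str = "") -> HeteroplasmyCall:
    """Heteroplasmic iff >= 2 haplotypes exceed ``threshold`` after removing
    any haplotype explained by the matched host's germline haplotype."""
    if not haplotype_fractions:
        raise ValueError("empty haplotype fraction map")
    total = sum(haplotype_fractions.values())
    if abs(total - 1.0) > 0.02:
        raise ValueError(f"fractions sum to {total:.3f}, expected 1")
    unexplained = {h: f for h, f in haplotype_fractions.items()
                   if h != host_haplotype}
    n_above = sum(1 for f in unexplained.values() if f > threshold)
    return HeteroplasmyCall(
        tumour_id=tumour_id,
        fractions=tuple(sorted(haplotype_fractions.items())),
        host_haplotype=host_haplotype,
        is_heteroplasmic=n_above >= 2,
    )


def estimate_haplotype_fractions(sample_vafs: Mapping[Variant, float],
                                 profiles: Mapping[str, Iterable[Variant]],
                                 min_fraction: float = 0.05
                                 ) -> dict[str, float]:
    """Decompose a tumour's variant VAFs into per-haplotype fractions.

    Candidate haplotypes are profiles for which at least half of the
    profile's variants are observed; each candidate's fraction is the
    median VAF over the variants that discriminate it from the other
    candidates, renormalised to sum to one.
    """
    observed = {v: f for v, f in sample_vafs.items() if f > 0.02}
    candidates: dict[str, set[Variant]] = {}
    for name, vs in profiles.items():
        vs = set(vs)
        if vs and sum(1 for v in vs if v in observed) >= len(vs) / 2:
            candidates[name] = vs
    fractions: dict[str, float] = {}
    for name, vs in candidates.items():
        others = set().union(*(v for n, v in candidates.items() if n != name)) \
            if len(candidates) > 1 else set()
        discrim = [observed.get(v, 0.0) for v in vs - others]
        if discrim:
            frac = float(sorted(discrim)[len(discrim) // 2])
            if frac >= min_fraction:
                fractions[name] = frac
    total = sum(fractions.values())
    if total > 0:
        fractions = {h: f / total for h, f in fractions.items()}
    return fractions


# ---------------------------------------------------------------------------
# Variant classification within an event
# ---------------------------------------------------------------------------

def classify_group_variants(event: HTEvent, variant_table: VariantTable,
                            donor_profile: Iterable[Variant]
                            ) -> tuple[dict[str, set[Variant]],
                                       frozenset[Variant]]:
    """Split non-donor variants into somatic-polymorphic and fixed-unknown.

    A variant absent from the donor profile that is present in *all*
    members is fixed within the group and its somatic/germline status is
    unknowable; one present in a strict subset is a confident somatic
    mutation.  For a singleton event every private variant is fixed-unknown.
    Returns ``(per-member somatic variant sets, fixed-unknown set)``.
    """
    donor = set(donor_profile)
    table_samples = set(variant_table.samples())
    absent = set(event.members) - table_samples
    if absent:
        raise ValueError(f"members missing from variant table: {sorted(absent)}")
    member_vars = {m: variant_table.variants_of(m) - donor
                   for m in event.members}
    all_private = set().union(*member_vars.values()) if member_vars else set()
    fixed = {v for v in all_private
             if all(v in mv for mv in member_vars.values())}
    somatic = {m: mv - fixed for m, mv in member_vars.items()}
    return somatic, frozenset(fixed)


def infer_event_location(event: HTEvent,
                         sample_locations: Mapping[str, str],
                         nuclear_tree: dendropy.Tree | None = None) -> str:
    """Unanimous member location, else the parsimony ancestral location of
    the event clade (if it is a singleton state set), else "ambiguous"."""
    missing = [m for m in event.members if m not in sample_locations]
    if missing:
        raise ValueError(f"members without location: {missing}")
    locs = {sample_locations[m] for m in event.members}
    if len(locs) == 1:
        return locs.pop()
    if nuclear_tree is None:
        return "ambiguous"
    tips = {leaf.taxon.label for leaf in nuclear_tree.leaf_node_iter()
            if leaf.taxon}
    states = {t: sample_locations.get(t) for t in tips}
    taxa = [nuclear_tree.taxon_namespace.get_taxon(m) for m in event.members]
    mrca = nuclear_tree.mrca(taxa=taxa)
    mpr, _ = sankoff_mpr(nuclear_tree, states)
    anc = mpr[mrca]
    return next(iter(anc)) if len(anc) == 1 else "ambiguous"


# ---------------------------------------------------------------------------
# Haplotype-specific variants and somatic recurrence
# ---------------------------------------------------------------------------

def discover_haplotype_specific_variants(
        target_haplotype: str,
        profiles: Mapping[str, Iterable[Variant]],
        allow_shared_with: set[str] | None = None) -> frozenset[Variant]:
    """Variants of the target profile absent from every other profile,
    except profiles listed in ``allow_shared_with``."""
    if target_haplotype not in profiles:
        raise ValueError(f"unknown haplotype {target_haplotype!r}")
    allow = set(allow_shared_with or ())
    target = set(profiles[target_haplotype])
    for name, vs in profiles.items():
        if name == target_haplotype or name in allow:
            continue
        target -= set(vs)
    return frozenset(target)


def count_somatic_recurrence(variant: Variant, variant_table: VariantTable,
                             tumour_haplotypes: Mapping[str, str],
                             exclude_haplotypes: set[str] | None = None,
                             events: Iterable[HTEvent] = ()) -> int:
    """Count independent somatic occurrences of ``variant``.

    Carrier tumours whose assigned haplotype is in ``exclude_haplotypes``
    are skipped (the variant is germline there); carriers within one HT
    event collapse to a single occurrence.
    """
    exclude = exclude_haplotypes or set()
    carriers = {s for s in variant_table.carriers(variant)
                if tumour_haplotypes.get(s) not in exclude}
    event_of = {m: e.event_id for e in events for m in e.members}
    occurrences = {event_of.get(s, f"__tumour__{s}") for s in carriers}
    return len(occurrences)
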