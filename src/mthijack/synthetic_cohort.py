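"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the study system: a host-dog population drawn from
18 haplogroup frequencies; a clonal tumour lineage whose nuclear tree
contains horizontal-transfer (HT) events as clean clades; Poisson somatic
mtDNA mutations accumulating at a fixed rate per year since each transfer;
heteroplasmic transfers carrying donor and incumbent haplotypes at a
configured fraction; read-support summaries for the substitution filter and
copy-number formula; long-read allele patterns for a recombinant tumour;
and negative-binomial expression counts with batch structure and a
configurable mtDNA transcript decrease.

Default parameter values are the study conditions: 495 dogs, 539 tumours,
19 HT events with the published donor/replaced/size/heteroplasmy structure,
mutation rate 0.0201 mutations/year, heteroplasmic fractions 0.55 and 0.15,
and one recombinant event.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import reference as ref
from .recombination_phasing import ReadAllelePattern
from .transcript_abundance import CountMatrix
from .variant_store import Variant, VariantTable, write_variant_table

# Default 19-event structure (donor, size, host event index or None for a
# founding lineage, age in years, heteroplasmy fraction or None).
_DEFAULT_EVENTS = [
    # donor,   size, host, age,   het
    ("A1e",    205, None, 469.28, None),   # HT1 founding lineage
    ("A1a1",   285, 0,    469.28, None),   # HT2
    ("A1d1a",  2,   0,    29.4,   None),   # HT3 (recombinant)
    ("A1a1",   6,   0,    100.0,  None),   # HT4
    ("A1d1",   2,   1,    100.0,  None),   # HT5
    ("A1a1",   2,   0,    50.0,   None),   # HT6
    ("A1a1",   1,   0,    50.0,   None),   # HT7
    ("A1d1a",  7,   0,    29.4,   None),   # HT8
    ("A1d1a",  14,  0,    29.4,   None),   # HT9
    ("A1d1a",  1,   0,    29.4,   None),   # HT10
    ("A1d1a",  1,   0,    29.4,   None),   # HT11
    ("A1d1a",  1,   0,    29.4,   None),   # HT12
    ("A1d1a",  1,   0,    29.4,   None),   # HT13
    ("A1d1a",  1,   1,    29.4,   None),   # HT14
    ("A1d1a",  1,   1,    29.4,   None),   # HT15
    ("A1d1a",  3,   1,    29.4,   None),   # HT16
    ("A1d1a",  4,   1,    29.4,   None),   # HT17
    ("B1",     1,   0,    10.0,   0.55),   # HT18
    ("A1a1",   1,   0,    10.0,   0.15),   # HT19
]

_LOCATIONS = ["Nicaragua", "Belize", "Chile", "Colombia", "Grenada", "India",
              "Paraguay", "The Gambia", "Mexico", "Armenia", "Nigeria",
              "Widespread"]


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort."""

    n_dogs: int = 495
    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(ref.DEFAULT_HAPLOTYPE_FREQS))
    n_tumours: int = 539
    n_ht_events: int = 19
    ht_donor_haplotypes: list[str] | None = None
    event_sizes: list[int] | None = None
    event_ages: list[float] | None = None
    heteroplasmy_fractions: dict[int, float] | None = None
    mutation_rate: float = 0.0201
    recombinant_event: int | None = None
    recombination_breakpoints: tuple[float, float] = (16000.0, 2500.0)
    genome_length: int = ref.GENOME_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumours == 539 and self.n_ht_events == 19 and \
                self.ht_donor_haplotypes is None:
            self.ht_donor_haplotypes = [e[0] for e in _DEFAULT_EVENTS]
            if self.event_sizes is None:
                self.event_sizes = [e[1] for e in _DEFAULT_EVENTS]
            if self.event_ages is None:
                self.event_ages = [e[3] for e in _DEFAULT_EVENTS]
            if self.heteroplasmy_fractions is None:
                self.heteroplasmy_fractions = {
                    i: e[4] for i, e in enumerate(_DEFAULT_EVENTS)
                    if e[4] is not None}
            if self.recombinant_event is None:
                self.recombinant_event = 2
        if self.heteroplasmy_fractions is None:
            self.heteroplasmy_fractions = {}
        self.validate()

    def validate(self) -> None:
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"haplotype_freqs sum to {total!r}, expected 1")
        if any(f < 0 for f in self.haplotype_freqs.values()):
            raise ConfigError("haplotype frequencies must be >= 0")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be > 0")
        if self.n_ht_events > self.n_tumours:
            raise ConfigError("n_ht_events > n_tumours")
        if self.n_ht_events < 1 or self.n_tumours < 1:
            raise ConfigError("need >= 1 event and >= 1 tumour")
        if self.mutation_rate < 0:
            raise ConfigError("mutation_rate must be >= 0")
        for f in self.heteroplasmy_fractions.values():
            if not 0 < f < 1:
                raise ConfigError(f"heteroplasmy fraction {f} outside (0, 1)")
        if self.event_ages is not None and any(a < 0 for a in self.event_ages):
            raise ConfigError("event ages must be >= 0")
        if self.event_sizes is not None:
            if sum(self.event_sizes) != self.n_tumours:
                raise ConfigError("event sizes must sum to n_tumours")
            if len(self.event_sizes) != self.n_ht_events:
                raise ConfigError("need one size per event")


@dataclass
class GroundTruth:
    """Per-tumour and per-event truth for downstream recovery checks."""

    tumours: pd.DataFrame  # tumour, event_id, donor, replaced, het_fraction,
    #                        n_somatic, host_haplotype, location
    events: pd.DataFrame   # event_id, donor, replaced, size, age, het, recomb
    breakpoints: tuple[float, float] | None = None


@dataclass
class Cohort:
    config: SimulationConfig
    nuclear_tree: dendropy.Tree
    variants: VariantTable
    truth: GroundTruth
    dogs: pd.DataFrame


# ---------------------------------------------------------------------------
# Dog population
# ---------------------------------------------------------------------------

def simulate_dog_population(config: SimulationConfig) -> pd.DataFrame:
    """Multinomial draw of germline haplotypes for the host-dog population.

    Each dog's mtDNA variant profile equals its haplogroup's reference
    profile; the returned frame has columns ``dog_id, haplotype``.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.haplotype_freqs)
    probs = np.array([config.haplotype_freqs[n] for n in names])
    counts = rng.multinomial(config.n_dogs, probs)
    haps = np.repeat(names, counts)
    rng.shuffle(haps)
    return pd.DataFrame({
        "dog_id": [f"D{i + 1:04d}" for i in range(config.n_dogs)],
        "haplotype": haps,
    })


# ---------------------------------------------------------------------------
# Tumour cohort
# ---------------------------------------------------------------------------

def _random_subtree(labels: Sequence[str], taxa: dendropy.TaxonNamespace,
                    rng: np.random.Generator) -> dendropy.Node:
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    for n in nodes:
        n.edge.length = 1.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = 1.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def _draw_event_structure(config: SimulationConfig, rng: np.random.Generator):
    """Sizes, donors and host events satisfying the cleanliness constraints:
    a grafted event's donor differs from its host's donor, and hosts have
    >= 2 members."""
    k = config.n_ht_events
    if config.event_sizes is not None:
        sizes = list(config.event_sizes)
    else:
        extra = rng.multinomial(config.n_tumours - k, np.full(k, 1.0 / k))
        sizes = (1 + extra).tolist()
    if k > 1 and config.event_sizes is None:
        # the founding lineage hosts most grafts; give it the largest size
        big = int(np.argmax(sizes))
        sizes[0], sizes[big] = sizes[big], sizes[0]
    if k > 1 and sizes[0] < 2:
        raise ConfigError("founding event needs >= 2 tumours to host grafts")

    names = list(config.haplotype_freqs)
    probs = np.array([config.haplotype_freqs[n] for n in names])
    probs = probs / probs.sum()

    donors = list(config.ht_donor_haplotypes or [])
    if donors and len(donors) != k:
        raise ConfigError("need one donor haplotype per event")
    if not donors:
        donors = [str(rng.choice(names, p=probs)) for _ in range(k)]

    if config.n_tumours == 539 and k == 19 and config.event_sizes is not None \
            and config.ht_donor_haplotypes == [e[0] for e in _DEFAULT_EVENTS]:
        hosts = [e[2] for e in _DEFAULT_EVENTS]
    else:
        # A graft must leave every event recoverable as a change-free
        # parsimony region: the donor must differ from the host's donor and
        # from the host's own background (otherwise relabelling the host
        # spine bridges the new clade into the surrounding region), and per
        # host the number of same-donor grafts stays below the tip count
        # (otherwise relabelling the whole host region is equally
        # parsimonious).
        hosts: list[int | None] = [None]
        graft_counts: list[dict[str, int]] = [dict() for _ in range(k)]
        graft_totals = [0] * k
        replaced_of: list[str | None] = [None] * k

        def eligible_hosts(e: int, donor: str) -> list[int]:
            out = []
            for h in range(e):
                if sizes[h] < 2 or donors[h] == donor:
                    continue
                if replaced_of[h] is not None and donor == replaced_of[h]:
                    continue
                if graft_totals[h] >= sizes[h]:  # every graft uses a new tip
                    continue
                if graft_counts[h].get(donor, 0) + 1 <= sizes[h] - 2:
                    out.append(h)
            return out

        for e in range(1, k):
            pool = eligible_hosts(e, donors[e])
            for _ in range(100):
                if pool:
                    break
                donors[e] = str(rng.choice(names, p=probs))
                pool = eligible_hosts(e, donors[e])
            if not pool:
                for cand in names:
                    pool = eligible_hosts(e, cand)
                    if pool:
                        donors[e] = cand
                        break
            if not pool:
                raise ConfigError(
                    "cannot place events without ambiguous clades; "
                    "use fewer events or larger event sizes")
            h = int(rng.choice(pool))
            hosts.append(h)
            graft_counts[h][donors[e]] = graft_counts[h].get(donors[e], 0) + 1
            graft_totals[h] += 1
            replaced_of[e] = donors[h]

    ages = list(config.event_ages) if config.event_ages is not None else \
        [float(a) for a in rng.uniform(5.0, 500.0, size=k)]
    if len(ages) != k:
        raise ConfigError("need one age per event")
    return sizes, donors, hosts, ages


def simulate_ctvt_cohort(config: SimulationConfig) -> Cohort:
    """Full synthetic tumour cohort: nuclear tree, variant table and truth."""
    rng = np.random.default_rng(config.seed)
    profiles = ref.builtin_profiles()
    unknown = set(config.haplotype_freqs) - set(profiles)
    if unknown:
        raise ConfigError(f"haplotypes without profiles: {sorted(unknown)}")

    sizes, donors, hosts, ages = _draw_event_structure(config, rng)
    k = config.n_ht_events
    tumour_ids = [f"T{i + 1:04d}" for i in range(config.n_tumours)]
    members: list[list[str]] = []
    start = 0
    for s in sizes:
        members.append(tumour_ids[start:start + s])
        start += s

    taxa = dendropy.TaxonNamespace(tumour_ids)
    event_roots = [_random_subtree(m, taxa, rng) for m in members]
    leaf_nodes: dict[str, dendropy.Node] = {}
    for root in event_roots:
        for leaf in root.leaf_iter():
            leaf_nodes[leaf.taxon.label] = leaf

    # graft each non-founding event above an unused tip of its host event
    free_tips = {e: list(m) for e, m in enumerate(members)}
    tree_root = event_roots[0]
    for e in range(1, k):
        h = hosts[e]
        if h is None:
            raise ConfigError("only the first event may be a founding lineage")
        if not free_tips[h]:
            raise ConfigError(f"host event {h} has no free tips left")
        tip_label = free_tips[h].pop(int(rng.integers(len(free_tips[h]))))
        tip = leaf_nodes[tip_label]
        parent = tip.parent_node
        joint = dendropy.Node()
        joint.edge.length = 1.0
        if parent is None:  # host subtree is a single tip (root)
            joint.add_child(tip)
            joint.add_child(event_roots[e])
            tree_root = joint
        else:
            parent.remove_child(tip)
            joint.add_child(tip)
            joint.add_child(event_roots[e])
            parent.add_child(joint)

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=tree_root)
    tree.is_rooted = True

    # per-tumour variant calls and somatic mutations
    profile_positions = {v.position for p in profiles.values() for v in p}
    seq = ref.reference_sequence()
    rows: list[dict] = []
    t_rows: list[dict] = []
    event_locations = [str(rng.choice(_LOCATIONS)) for _ in range(k)]
    dog_names = list(config.haplotype_freqs)
    dog_probs = np.array([config.haplotype_freqs[n] for n in dog_names])
    dog_probs = dog_probs / dog_probs.sum()

    for e in range(k):
        donor_prof = set(profiles[donors[e]])
        het = config.heteroplasmy_fractions.get(e)
        replaced = donors[hosts[e]] if hosts[e] is not None else "Unknown"
        incumbent_prof = set(profiles[replaced]) if replaced != "Unknown" else set()
        lam = config.mutation_rate * ages[e]
        for tumour in members[e]:
            frac = het if het is not None else 1.0
            calls: dict[Variant, float] = {}
            for v in donor_prof:
                calls[v] = 1.0 if (het is not None and v in incumbent_prof) \
                    else frac
            if het is not None:
                for v in incumbent_prof - donor_prof:
                    calls[v] = 1.0 - frac
            n_somatic = int(rng.poisson(lam))
            used = {v.position for v in calls}
            placed = 0
            while placed < n_somatic:
                pos = int(rng.integers(1, config.genome_length + 1))
                if pos in profile_positions or pos in used:
                    continue
                base = seq[(pos - 1) % len(seq)]
                alts = [b for b in "ACGT" if b != base]
                calls[Variant(pos, base, alts[int(rng.integers(3))])] = frac
                used.add(pos)
                placed += 1
            for v, f in calls.items():
                rows.append({"sample": tumour, "chrom": "MT",
                             "pos": v.position, "ref": v.ref, "alt": v.alt,
                             "supporting_reads": np.nan,
                             "total_reads": np.nan, "vaf": f})
            t_rows.append({
                "tumour": tumour, "event_id": f"HT{e + 1}",
                "donor": donors[e], "replaced": replaced,
                "het_fraction": frac, "n_somatic": n_somatic,
                "host_haplotype": str(rng.choice(dog_names, p=dog_probs)),
                "location": event_locations[e],
            })

    variants = VariantTable(pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt",
                       "supporting_reads", "total_reads", "vaf"]),
        genome_length=config.genome_length)
    events_df = pd.DataFrame({
        "event_id": [f"HT{e + 1}" for e in range(k)],
        "donor": donors,
        "replaced": [donors[hosts[e]] if hosts[e] is not None else "Unknown"
                     for e in range(k)],
        "size": sizes,
        "age": ages,
        "het_fraction": [config.heteroplasmy_fractions.get(e, 1.0)
                         for e in range(k)],
        "recombinant": [e == config.recombinant_event for e in range(k)],
        "location": event_locations,
    })
    truth = GroundTruth(
        tumours=pd.DataFrame(t_rows), events=events_df,
        breakpoints=(config.recombination_breakpoints
                     if config.recombinant_event is not None else None))
    dogs = simulate_dog_population(config)
    return Cohort(config=config, nuclear_tree=tree, variants=variants,
                  truth=truth, dogs=dogs)


# ---------------------------------------------------------------------------
# Read support
# ---------------------------------------------------------------------------

@dataclass
class ReadSupport:
    pileup: pd.DataFrame          # sample,pos,ref,alt,mq,bq per supporting read
    coverage: pd.DataFrame        # sample, mt_coverage, nuclear_coverage
    nuclear_somatic_vafs: dict[str, np.ndarray]
    observed_mt_vafs: pd.DataFrame  # sample,pos,ref,alt,supporting,total,vaf


def simulate_read_support(variant_table: VariantTable, mean_mt_depth: float,
                          mean_nuc_depth: float, tumour_fraction: float,
                          seed: int, mt_tumour_fraction: float = 1.0,
                          n_nuclear_sites: int = 500,
                          max_pileup_reads: int = 200) -> ReadSupport:
    """Binomial read support and quality annotations for every variant call.

    Supporting counts are Binomial(depth, VAF x mt tumour fraction); each
    supporting read carries a mapping and base quality (per-read quality
    rows are capped at ``max_pileup_reads`` per variant; the counts in
    ``observed_mt_vafs`` are always exact).  Nuclear somatic VAFs
    concentrate near ``tumour_fraction / 2`` (diploid heterozygous).
    """
    if mean_mt_depth <= 0 or mean_nuc_depth <= 0:
        raise ValueError("depths must be > 0")
    if not 0 < tumour_fraction <= 1:
        raise ValueError("tumour_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    depth = int(round(mean_mt_depth))
    nuc_depth = int(round(mean_nuc_depth))

    pile_rows, obs_rows = [], []
    for r in variant_table.df.itertuples(index=False):
        p_obs = min(r.vaf * mt_tumour_fraction, 1.0)
        support = int(rng.binomial(depth, p_obs))
        for _ in range(min(support, max_pileup_reads)):
            mq = 60 if rng.random() > 0.05 else int(rng.integers(0, 20))
            bq = int(np.clip(rng.normal(35, 6), 2, 45))
            pile_rows.append({"sample": r.sample, "pos": r.pos, "ref": r.ref,
                              "alt": r.alt, "mq": mq, "bq": bq})
        obs_rows.append({"sample": r.sample, "pos": r.pos, "ref": r.ref,
                         "alt": r.alt, "supporting_reads": support,
                         "total_reads": depth,
                         "vaf": support / depth})
    samples = variant_table.samples()
    coverage = pd.DataFrame({
        "sample": samples,
        "mt_coverage": mean_mt_depth * rng.normal(1.0, 0.03, len(samples)),
        "nuclear_coverage": mean_nuc_depth * rng.normal(1.0, 0.03, len(samples)),
    })
    nuclear = {
        s: rng.binomial(nuc_depth, tumour_fraction / 2, n_nuclear_sites)
        / nuc_depth
        for s in samples
    }
    return ReadSupport(
        pileup=pd.DataFrame(pile_rows,
                            columns=["sample", "pos", "ref", "alt", "mq", "bq"]),
        coverage=coverage,
        nuclear_somatic_vafs=nuclear,
        observed_mt_vafs=pd.DataFrame(obs_rows))


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def simulate_expression_counts(group_sizes: Mapping[str, int],
                               affected_group: str,
                               n_genes_mt: int = 13,
                               n_genes_nuclear: int = 7,
                               n_genes_other: int = 2000,
                               n_batches: int = 2,
                               effect_fraction: float = 0.39,
                               dispersion: float = 0.15,
                               seed: int = 0,
                               affected_genes: Sequence[str] | None = None
                               ) -> CountMatrix:
    """Negative-binomial counts with batch structure and an mtDNA effect.

    mtDNA-gene means in ``affected_group`` are scaled by
    ``1 - effect_fraction`` (all mtDNA genes by default, or only
    ``affected_genes``); nuclear and background ("other") genes are never
    scaled.  The background genes anchor the median-of-ratios size factors,
    as the genome-wide transcriptome does in a real count matrix.  Batch
    effects are multiplicative per-batch per-gene factors.
    """
    if not 0 <= effect_fraction < 1:
        raise ConfigError("effect_fraction must be in [0, 1)")
    if any(n < 2 for n in group_sizes.values()):
        raise ConfigError("each group needs >= 2 samples")
    if affected_group not in group_sizes:
        raise ConfigError(f"unknown group {affected_group!r}")
    rng = np.random.default_rng(seed)

    mt_genes = [f"MT-G{i + 1}" for i in range(n_genes_mt)]
    nuc_genes = [f"NUC-G{i + 1}" for i in range(n_genes_nuclear)]
    other_genes = [f"BG-G{i + 1}" for i in range(n_genes_other)]
    genes = mt_genes + nuc_genes + other_genes
    classes = pd.Series(["mtDNA"] * n_genes_mt + ["nuclear"] * n_genes_nuclear
                        + ["other"] * n_genes_other,
                        index=genes, name="gene_class")
    affected = set(affected_genes if affected_genes is not None else mt_genes)
    bad = affected - set(mt_genes)
    if bad:
        raise ConfigError(f"affected genes must be mtDNA genes: {sorted(bad)}")

    base = np.concatenate([
        np.exp(rng.normal(np.log(2000.0), 0.5, n_genes_mt)),
        np.exp(rng.normal(np.log(800.0), 0.5, n_genes_nuclear)),
        np.exp(rng.normal(np.log(300.0), 1.0, n_genes_other)),
    ])
    batch_factor = np.exp(rng.normal(0.0, 0.25, size=(len(genes), n_batches)))

    sample_ids, groups, batches = [], [], []
    for gname, n in group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{gname}_S{i + 1}")
            groups.append(gname)
            batches.append(f"batch{i % n_batches + 1}")
    samples = pd.DataFrame({"group": groups, "batch": batches},
                           index=pd.Index(sample_ids, name="sample"))

    affected_mask = np.array([g in affected for g in genes])
    batch_idx = np.array([int(b.removeprefix("batch")) - 1 for b in batches])
    mu = base[:, None] * batch_factor[:, batch_idx]
    in_group = np.array([g == affected_group for g in groups])
    mu[np.ix_(affected_mask, in_group)] *= (1.0 - effect_fraction)
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        gene_classes=classes, samples=samples)


# ---------------------------------------------------------------------------
# Recombinant long reads
# ---------------------------------------------------------------------------

@dataclass
class RecombinantReadSim:
    reads: list[ReadAllelePattern]
    parent_a_alleles: dict[int, str]
    parent_b_alleles: dict[int, str]
    donor_site_variants: dict[int, tuple[str, Variant]]
    universal_variant: Variant
    true_haplotypes: list[dict[int, str]]
    true_fractions: tuple[float, ...]


def simulate_recombinant_reads(seed: int, parent_a: str = "A1d1a",
                               parent_b: str = "A1e",
                               haplotype_fractions: Sequence[float] = (0.5, 0.3, 0.2),
                               n_reads: int = 300,
                               noise: float = 0.02) -> RecombinantReadSim:
    """Long-read allele patterns from a recombinant heteroplasmic tumour.

    Within-tumour haplotypes are mosaics of the two parental profiles over
    their diagnostic sites; the donor's control-region insertion (the
    16660insCC analogue) is carried by *all* haplotypes, while every other
    donor-specific site is mosaic.  A ``noise`` fraction of reads carries
    one miscalled site.
    """
    rng = np.random.default_rng(seed)
    profiles = ref.builtin_profiles()
    prof_a, prof_b = set(profiles[parent_a]), set(profiles[parent_b])

    sites: dict[int, tuple[str, str]] = {}
    donor_site_variants: dict[int, tuple[str, Variant]] = {}
    for v in prof_a - prof_b:
        sites[v.position] = (v.alt, v.ref)
        donor_site_variants[v.position] = (v.alt, v)
    for v in prof_b - prof_a:
        sites[v.position] = (v.ref, v.alt)
    positions = sorted(sites)
    universal = next(v for _, v in donor_site_variants.values()
                     if v.kind == "insertion")
    u_idx = positions.index(universal.position)
    n_sites = len(positions)
    mosaic_targets = [p for p in donor_site_variants if p != universal.position]

    for _ in range(500):
        hap_parents = []
        for _h in haplotype_fractions:
            n_bp = int(rng.choice([2, 2, 4]))
            gaps = sorted(rng.choice(n_sites, size=n_bp, replace=False))
            parent = np.empty(n_sites, dtype="<U1")
            current = "A"
            g = 0
            for i in range(n_sites):
                while g < len(gaps) and gaps[g] == i:
                    current = "B" if current == "A" else "A"
                    g += 1
                parent[i] = current
            if parent[u_idx] != "A":
                parent = np.where(parent == "A", "B", "A")
            hap_parents.append(parent)
        distinct = len({tuple(h) for h in hap_parents}) == len(hap_parents)
        mosaic_ok = all(
            any(h[positions.index(p)] == "B" for h in hap_parents)
            for p in mosaic_targets)
        if distinct and mosaic_ok:
            break
    else:  # pragma: no cover - rejection loop converges quickly
        raise RuntimeError("could not construct mosaic haplotypes")

    true_haps = []
    for parent in hap_parents:
        true_haps.append({
            positions[i]: (sites[positions[i]][0] if parent[i] == "A"
                           else sites[positions[i]][1])
            for i in range(n_sites)})

    fractions = np.asarray(haplotype_fractions, dtype=float)
    fractions = fractions / fractions.sum()
    reads = []
    min_span = max(2, int(0.6 * n_sites))  # unsheared long reads span most
    for r in range(n_reads):               # of the circular genome
        hap = true_haps[int(rng.choice(len(true_haps), p=fractions))]
        length = int(rng.integers(min_span, n_sites + 1))
        start = int(rng.integers(n_sites))
        covered = [positions[(start + i) % n_sites] for i in range(length)]
        alleles = {p: hap[p] for p in covered}
        if rng.random() < noise:
            flip = covered[int(rng.integers(len(covered)))]
            a, b = sites[flip]
            alleles[flip] = b if alleles[flip] == a else a
        reads.append(ReadAllelePattern(
            read_id=f"read{r + 1:04d}",
            alleles=tuple(sorted(alleles.items()))))
    return RecombinantReadSim(
        reads=reads,
        parent_a_alleles={p: sites[p][0] for p in positions},
        parent_b_alleles={p: sites[p][1] for p in positions},
        donor_site_variants=donor_site_variants,
        universal_variant=universal,
        true_haplotypes=true_haps,
        true_fractions=tuple(fractions.tolist()))


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------

def apply_variants(sequence: str, variants: set[Variant]) -> str:
    """Apply substitutions and indels to a linearised reference sequence."""
    seq = list(sequence)
    for v in sorted(variants, key=lambda v: -v.position):
        i = v.position - 1
        if v.kind == "substitution":
            seq[i] = v.alt
        elif v.kind == "insertion":
            seq[i] = v.alt
        else:
            del seq[i + 1:i + 1 + (len(v.ref) - len(v.alt))]
            seq[i] = v.alt
    return "".join(seq)


def write_fixture_bundle(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as FASTA + VCF + TSV + newick; round-trip exact."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["variants"] = directory / "variants.tsv"
    cohort.variants.df.to_csv(paths["variants"], sep="\t", index=False)

    paths["tree"] = directory / "nuclear_tree.nwk"
    cohort.nuclear_tree.write(path=str(paths["tree"]), schema="newick",
                              unquoted_underscores=True, suppress_rooting=True)

    paths["dogs"] = directory / "dogs.tsv"
    cohort.dogs.to_csv(paths["dogs"], sep="\t", index=False)
    paths["truth_tumours"] = directory / "ground_truth_tumours.tsv"
    cohort.truth.tumours.to_csv(paths["truth_tumours"], sep="\t", index=False)
    paths["truth_events"] = directory / "ground_truth_events.tsv"
    cohort.truth.events.to_csv(paths["truth_events"], sep="\t", index=False)

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seq = ref.reference_sequence()
    records = []
    for sample in cohort.variants.samples():
        consensus = apply_variants(seq, cohort.variants.variants_of(sample, 0.5))
        records.append(SeqRecord(Seq(consensus), id=sample, description=""))
    paths["fasta"] = directory / "consensus.fasta"
    SeqIO.write(records, str(paths["fasta"]), "fasta")

    vcf_dir = directory / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample in cohort.variants.samples():
        sub = VariantTable(
            cohort.variants.df[cohort.variants.df["sample"] == sample],
            cohort.variants.genome_length)
        write_variant_table(sub, vcf_dir / f"{sample}.vcf", format="vcf")
    paths["vcf_dir"] = vcf_dir

    cfg = dataclasses.asdict(cohort.config)
    cfg["recombination_breakpoints"] = list(cfg["recombination_breakpoints"])
    paths["config"] = directory / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def read_fixture_bundle(directory: str | Path) -> Cohort:
    """Reload a cohort written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    cfg = yaml.safe_load((directory / "config.yaml").read_text())
    cfg["recombination_breakpoints"] = tuple(cfg["recombination_breakpoints"])
    het = cfg.get("heteroplasmy_fractions") or {}
    cfg["heteroplasmy_fractions"] = {int(k): float(v) for k, v in het.items()}
    config = SimulationConfig(**cfg)
    variants_df = pd.read_csv(directory / "variants.tsv", sep="\t")
    variants = VariantTable(variants_df, config.genome_length)
    tree = dendropy.Tree.get(path=str(directory / "nuclear_tree.nwk"),
                             schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    truth = GroundTruth(
        tumours=pd.read_csv(directory / "ground_truth_tumours.tsv", sep="\t"),
        events=pd.read_csv(directory / "ground_truth_events.tsv", sep="\t"),
        breakpoints=(config.recombination_breakpoints
                     if config.recombinant_event is not None else None))
    dogs = pd.read_csv(directory / "dogs.tsv", sep="\t")
    return Cohort(config=config, nuclear_tree=tree, variants=variants,
                  truth=truth, dogs=dogs)
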