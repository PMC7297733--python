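"""Phasing of recombinant mtDNA haplotypes from long-read allele patterns.

Long reads spanning multiple informative sites (sites that discriminate the
two parental haplotypes of a recombinant tumour) are clustered by exact
allele-pattern agreement; sites a read does not cover wildcard-match any
cluster.  Cluster frequencies estimate the within-tumour frequency of each
recombinant haplotype.  Ancestry segments are assigned per haplotype by
minimal-breakpoint segmentation on the circular genome, with breakpoints
placed midway between adjacent discordant informative sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variant_store import Variant


@dataclass(frozen=True)
class ReadAllelePattern:
    """Alleles observed on one read at the informative sites it covers."""

    read_id: str
    alleles: tuple[tuple[int, str], ...]  # (position, allele), sorted

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"read {self.read_id} covers no informative site")

    @property
    def site_map(self) -> dict[int, str]:
        return dict(self.alleles)


@dataclass
class RecombinantHaplotype:
    """A phased within-tumour haplotype over the informative sites."""

    alleles: dict[int, str]
    frequency: float
    n_reads: int
    low_level: bool = False
    segments: list[tuple[float, float, str]] = field(default_factory=list)
    breakpoints: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class PhasingResult:
    haplotypes: tuple[RecombinantHaplotype, ...]
    unassigned_fraction: float
    n_reads: int


def _compatible(consensus: Mapping[int, str], read: Mapping[int, str]) -> bool:
    shared = consensus.keys() & read.keys()
    return bool(shared) and all(consensus[p] == read[p] for p in shared)


def phase_long_reads(reads: Sequence[ReadAllelePattern],
                     min_report_fraction: float = 0.05,
                     min_reads: int = 3) -> PhasingResult:
    """Cluster reads into haplotypes by exact pattern agreement.

    Reads are processed in decreasing order of covered sites; a read joins
    the unique cluster it is compatible with (agreeing at every shared
    site), extending the cluster consensus at newly covered sites.  Reads
    compatible with several clusters are deferred and assigned to the
    largest compatible cluster; ties go to an unassigned pool.  Haplotypes
    below ``min_report_fraction`` are flagged low-level, not dropped;
    clusters with fewer than ``min_reads`` supporting reads are unreportable
    (single miscalled reads masquerade as haplotypes) and their reads move
    to the unassigned pool.
    """
    if len(reads) < 10:
        raise ValueError("need >= 10 reads for phasing")
    all_sites = set()
    for r in reads:
        all_sites |= r.site_map.keys()
    coverage_ok = any(len(set(a.site_map) & set(b.site_map)) >= 2
                      for a in reads[:50] for b in reads[:50] if a is not b)
    if len(all_sites) < 2 or not coverage_ok:
        raise ValueError("reads share fewer than 2 informative sites")

    ordered = sorted(reads, key=lambda r: (-len(r.alleles), r.read_id))
    clusters: list[dict] = []  # consensus {pos: allele}, n, per-site coverage
    deferred: list[ReadAllelePattern] = []

    def join(cluster, rmap):
        cluster["n"] += 1
        for p, a in rmap.items():
            cluster["consensus"].setdefault(p, a)
            cluster["cov"][p] = cluster["cov"].get(p, 0) + 1

    for read in ordered:
        rmap = read.site_map
        hits = [c for c in clusters if _compatible(c["consensus"], rmap)]
        if len(hits) == 1:
            join(hits[0], rmap)
        elif not hits:
            clusters.append({"consensus": dict(rmap), "n": 1,
                             "cov": {p: 1 for p in rmap}})
        else:
            deferred.append(read)

    unassigned = 0
    for read in deferred:
        hits = [c for c in clusters if _compatible(c["consensus"], read.site_map)]
        sizes = sorted({c["n"] for c in hits}, reverse=True)
        top = [c for c in hits if c["n"] == sizes[0]] if hits else []
        if len(top) == 1:
            join(top[0], read.site_map)
        else:
            unassigned += 1

    # error absorption: a small cluster whose disagreement with a larger
    # cluster rests on weakly covered sites (one member read) is a
    # read-error artefact, not a haplotype; when a cluster is >= 20x
    # larger, even one strongly covered conflicting site is more plausibly
    # a recurrent miscall than a distinct haplotype.  Merge into the
    # largest qualifying cluster.
    for cluster in sorted(clusters, key=lambda c: c["n"]):
        if cluster["n"] == 0:
            continue
        strong = {p: a for p, a in cluster["consensus"].items()
                  if cluster["cov"].get(p, 0) >= 2}
        if not strong:
            continue
        targets = []
        for c in clusters:
            if c is cluster or c["n"] <= cluster["n"]:
                continue
            shared = strong.keys() & c["consensus"].keys()
            conflicts = sum(1 for p in shared
                            if c["consensus"][p] != strong[p])
            if shared and (conflicts == 0
                           or (conflicts <= 1
                               and c["n"] >= 20 * cluster["n"])):
                targets.append(c)
        if targets:
            target = max(targets, key=lambda c: c["n"])
            target["n"] += cluster["n"]
            cluster["n"] = 0

    reported = [c for c in clusters if c["n"] >= min_reads]
    unassigned += sum(c["n"] for c in clusters
                      if 0 < c["n"] < min_reads)

    total = len(reads)
    haplotypes = []
    for c in sorted(reported, key=lambda c: -c["n"]):
        freq = c["n"] / total
        haplotypes.append(RecombinantHaplotype(
            alleles=dict(sorted(c["consensus"].items())),
            frequency=freq, n_reads=c["n"],
            low_level=freq < min_report_fraction))
    return PhasingResult(haplotypes=tuple(haplotypes),
                         unassigned_fraction=unassigned / total,
                         n_reads=total)


# ---------------------------------------------------------------------------
# Ancestry segmentation
# ---------------------------------------------------------------------------

def segment_ancestry(haplotype: RecombinantHaplotype | Mapping[int, str],
                     parent_profile_a: Mapping[int, str],
                     parent_profile_b: Mapping[int, str],
                     genome_length: int = 16727
                     ) -> tuple[list[tuple[float, float, str]], list[float]]:
    """Minimal-breakpoint parental segmentation on the circular genome.

    Every informative site must be diagnostic (parents differ and the
    haplotype matches one of them).  Breakpoints sit midway between
    adjacent discordant sites; the returned segments tile the circle.
    On a circle the breakpoint count is always even (0 for a pure parent).
    """
    alleles = haplotype.alleles if isinstance(haplotype, RecombinantHaplotype) \
        else dict(haplotype)
    parents: list[tuple[int, str]] = []
    for pos in sorted(alleles):
        a, b = parent_profile_a.get(pos), parent_profile_b.get(pos)
        if a is None or b is None or a == b:
            raise ValueError(f"site {pos} is not diagnostic between parents")
        if alleles[pos] == a:
            parents.append((pos, "A"))
        elif alleles[pos] == b:
            parents.append((pos, "B"))
        else:
            raise ValueError(
                f"allele {alleles[pos]!r} at {pos} matches neither parent")

    breakpoints: list[float] = []
    n = len(parents)
    for i in range(n):
        (p1, par1), (p2, par2) = parents[i], parents[(i + 1) % n]
        if par1 != par2:
            if i + 1 < n:
                mid = (p1 + p2) / 2
            else:  # wrap-around gap through the origin
                gap = (p2 + genome_length) - p1
                mid = (p1 + gap / 2 - 1) % genome_length + 1
            breakpoints.append(round(mid, 1))

    if not breakpoints:
        segments = [(1.0, float(genome_length), parents[0][1])]
        return segments, []

    breakpoints.sort()
    segments = []
    for i, start in enumerate(breakpoints):
        end = breakpoints[(i + 1) % len(breakpoints)]
        # parent of this arc = parent of any site inside (start, end]
        parent = _parent_in_arc(parents, start, end, genome_length)
        segments.append((start, end, parent))
    return segments, breakpoints


def _parent_in_arc(parents: list[tuple[int, str]], start: float, end: float,
                   genome_length: int) -> str:
    for pos, par in parents:
        if start < end:
            inside = start < pos <= end
        else:
            inside = pos > start or pos <= end
        if inside:
            return par
    raise ValueError("empty arc in segmentation")  # pragma: no cover


# ---------------------------------------------------------------------------
# Variants fixed across all haplotypes
# ---------------------------------------------------------------------------

def fixed_variants(haplotype_variant_sets: Iterable[Iterable[Variant]],
                   donor_specific_variants: Iterable[Variant]
                   ) -> frozenset[Variant]:
    """Donor-specific variants carried by every reported haplotype
    (including low-level ones)."""
    sets = [set(h) for h in haplotype_variant_sets]
    if not sets:
        raise ValueError("need >= 1 haplotype")
    common = set.intersection(*sets)
    return frozenset(common & set(donor_specific_variants))


def haplotype_variant_set(haplotype: RecombinantHaplotype,
                          site_variants: Mapping[int, tuple[str, Variant]]
                          ) -> set[Variant]:
    """Translate a phased allele vector into carried donor variants.

    ``site_variants`` maps informative position -> (donor allele, Variant);
    the haplotype carries the variant where its allele equals the donor
    allele.
    """
    carried = set()
    for pos, (donor_allele, variant) in site_variants.items():
        if haplotype.alleles.get(pos) == donor_allele:
            carried.add(variant)
    return carried
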