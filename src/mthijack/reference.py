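"""Synthetic canine mtDNA reference and built-in haplogroup profiles.

The canine mitochondrial genome (CanFam3.1 convention) is circular with
length 16,727 bp.  Real haplogroup-defining variant sets are not bundled;
instead this module generates deterministic *synthetic stand-in* profiles
for the 18 canine haplogroups used in haplotype assignment (A1, A1a1, A1b,
A1c, A1d1, A1d1a, A1d2, A1e, A1f, A1h, A2, A4, A5, A6, B1, B2, C1, C2).
The stand-ins preserve the structural features that downstream analyses
depend on:

* a nested clade structure (A-clade > A1 > A1d > A1d1 > A1d1a, B-clade,
  C-clade) so that assignment distances and neighbour-joining recover the
  nomenclature hierarchy;
* A1d1a carries eight SNPs and one control-region insertion (the
  16660insCC analogue) that are unique to A1d1a or shared only with the
  related A1d1 haplotype;
* 16672C>T is carried by several haplotypes (A1d1a, A1e, B1), so it is
  *not* A1d1a-specific;
* 7593T>C is one of the A1d1a-private SNPs.

User-supplied real profiles (TSV: haplotype, pos, ref, alt) are accepted
everywhere a profile mapping is taken.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .variant_store import Variant

GENOME_LENGTH = 16727

#: Host-dog haplogroup frequencies used as the generator's default study
#: condition (synthetic stand-in for a representative global host-dog
#: population of ~495 dogs; A1d1a is prevalent but far from dominant).
DEFAULT_HAPLOTYPE_FREQS: dict[str, float] = {
    "A1": 0.04,
    "A1a1": 0.18,
    "A1b": 0.03,
    "A1c": 0.02,
    "A1d1": 0.05,
    "A1d1a": 0.22,
    "A1d2": 0.02,
    "A1e": 0.12,
    "A1f": 0.01,
    "A1h": 0.01,
    "A2": 0.05,
    "A4": 0.03,
    "A5": 0.02,
    "A6": 0.02,
    "B1": 0.10,
    "B2": 0.04,
    "C1": 0.03,
    "C2": 0.01,
}

HAPLOTYPE_NAMES = tuple(DEFAULT_HAPLOTYPE_FREQS)

_A_CLADE = [n for n in HAPLOTYPE_NAMES if n.startswith("A")]
_A1_GROUP = [n for n in HAPLOTYPE_NAMES if n.startswith("A1")]
_A1D_GROUP = ["A1d1", "A1d1a", "A1d2"]
_A1D1_GROUP = ["A1d1", "A1d1a"]
_B_CLADE = ["B1", "B2"]
_C_CLADE = ["C1", "C2"]

# Positions with a fixed, documented role (1-based).
INSERTION_POSITION = 16660  # control-region CC insertion anchor
NONSYN_SNP_POSITION = 7593  # T>C, protein-coding analogue
SHARED_CR_SNP_POSITION = 16672  # C>T, present on several haplotypes

_BASES = np.array(list("ACGT"))


@lru_cache(maxsize=1)
def reference_sequence() -> str:
    """Deterministic synthetic circular reference (length 16,727)."""
    rng = np.random.default_rng(16727)
    seq = rng.choice(_BASES, size=GENOME_LENGTH)
    # Fixed bases at documented positions (1-based -> 0-based).
    seq[NONSYN_SNP_POSITION - 1] = "T"
    seq[SHARED_CR_SNP_POSITION - 1] = "C"
    # Insertion context: anchor 'A' at 16660 followed by a CC run so that
    # a CC insertion reported inside the run left-aligns to 16660.
    seq[16659 - 1] = "T"
    seq[16660 - 1] = "A"
    seq[16661 - 1] = "C"
    seq[16662 - 1] = "C"
    seq[16663 - 1] = "T"
    return "".join(seq)


def _snp(pos: int, rng: np.random.Generator) -> Variant:
    ref = reference_sequence()[pos - 1]
    alts = [b for b in "ACGT" if b != ref]
    return Variant(pos, ref, alts[int(rng.integers(len(alts)))])


@lru_cache(maxsize=1)
def builtin_profiles() -> dict[str, frozenset[Variant]]:
    """Synthetic stand-in variant profiles for the 18 haplogroups."""
    rng = np.random.default_rng(46)
    reserved = {INSERTION_POSITION, NONSYN_SNP_POSITION, SHARED_CR_SNP_POSITION}
    reserved |= set(range(16655, 16670))  # keep the insertion context clean
    pool = [p for p in range(1, GENOME_LENGTH + 1) if p not in reserved]
    positions = iter(rng.choice(pool, size=400, replace=False).tolist())

    def snps(k: int) -> list[Variant]:
        return [_snp(next(positions), rng) for _ in range(k)]

    a_clade = snps(4)
    a1_shared = snps(3)
    a1d_shared = snps(2)
    a1d1_shared = snps(3)  # shared by A1d1 and A1d1a only
    b_clade = snps(4)
    c_clade = snps(4)

    ref = reference_sequence()
    ins_cc = Variant(INSERTION_POSITION, ref[INSERTION_POSITION - 1],
                     ref[INSERTION_POSITION - 1] + "CC")
    shared_cr = Variant(SHARED_CR_SNP_POSITION, "C", "T")
    nonsyn = Variant(NONSYN_SNP_POSITION, "T", "C")

    # A1d1a privates: 5 SNPs (incl. 7593T>C) + the insertion; together with
    # the 3 A1d1-shared SNPs this gives 8 SNPs + 1 insertion that are unique
    # to A1d1a or shared only with A1d1.
    a1d1a_private = [nonsyn] + snps(4) + [ins_cc]

    profiles: dict[str, set[Variant]] = {}
    for name in HAPLOTYPE_NAMES:
        prof: set[Variant] = set()
        if name in _A_CLADE:
            prof |= set(a_clade)
        if name in _A1_GROUP:
            prof |= set(a1_shared)
        if name in _A1D_GROUP:
            prof |= set(a1d_shared)
        if name in _A1D1_GROUP:
            prof |= set(a1d1_shared)
        if name in _B_CLADE:
            prof |= set(b_clade)
        if name in _C_CLADE:
            prof |= set(c_clade)
        if name == "A1d1a":
            prof |= set(a1d1a_private)
        else:
            prof |= set(snps(6))
        profiles[name] = prof

    for carrier in ("A1d1a", "A1e", "B1"):
        profiles[carrier].add(shared_cr)
    return {name: frozenset(v) for name, v in profiles.items()}


def a1d1a_specific_variants() -> frozenset[Variant]:
    """The 9 variants unique to A1d1a (or shared only with A1d1)."""
    profiles = builtin_profiles()
    others = [v for n, v in profiles.items() if n not in ("A1d1a", "A1d1")]
    other_union = frozenset().union(*others)
    return frozenset(profiles["A1d1a"] - other_union)
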