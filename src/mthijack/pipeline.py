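"""End-to-end orchestration: simulate, assign, detect, test, date, report.

The pipeline consumes a YAML configuration, runs the requested stages on a
synthetic cohort (or user-supplied inputs written in the same bundle
layout) and writes machine-readable reports: an event table mirroring the
published summary-table layout, enrichment and dating results, and a run
manifest with file digests.  All randomness flows from the single config
seed; two runs with the same config and seed produce byte-identical
reports (timestamps live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import reference as ref
from .copy_number import (CoverageSummary, compare_groups_ttest,
                          estimate_mt_tumour_fraction,
                          estimate_nuclear_tumour_fraction, mtdna_copy_number)
from .ht_detection import (HTEvent, call_heteroplasmy, classify_group_variants,
                           detect_ht_events, estimate_haplotype_fractions,
                           infer_event_location, infer_replaced_haplotype)
from .phylo_core import assign_haplotype
from .recombination_phasing import (fixed_variants, haplotype_variant_set,
                                    phase_long_reads)
from .selection_stats import calibrate_rate, date_ht_event, enrichment_test
from .synthetic_cohort import (Cohort, ConfigError, SimulationConfig,
                               simulate_ctvt_cohort, simulate_expression_counts,
                               simulate_read_support,
                               simulate_recombinant_reads, write_fixture_bundle)
from .transcript_abundance import (batch_correct, group_abundance_change,
                                   normalised_log_abundance,
                                   per_gene_differential)

ALL_STAGES = ["simulate", "assign", "detect", "enrich", "date",
              "copy_number", "phase", "expression"]

DEFAULT_RATE_ANCHOR = {"mean_mutations": 9.437, "divergence_years": 469.28,
                       "divergence_interval": [240.34, 744.31]}


def load_config(config_path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def validate_config(config_path: str | Path) -> list[str]:
    """Aggregate all configuration errors; empty list means valid."""
    errors: list[str] = []
    try:
        cfg = load_config(config_path)
    except Exception as exc:
        return [f"config unreadable: {exc}"]
    stages = cfg.get("stages", ALL_STAGES)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        errors.append(f"unknown stages: {unknown}")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
    sim = cfg.get("simulate", {})
    try:
        _simulation_config(cfg)
    except (ConfigError, TypeError, ValueError) as exc:
        errors.append(f"simulate: {exc}")
    if "enrich" in stages:
        enrich = cfg.get("enrich", {})
        if not isinstance(enrich.get("replicates", 10000), int):
            errors.append("enrich.replicates: must be an integer")
    if "expression" in stages:
        expr = cfg.get("expression", {})
        sizes = expr.get("group_sizes", {"A1d1a": 15, "CTVT_HT": 15})
        if not isinstance(sizes, dict) or any(
                not isinstance(v, int) or v < 2 for v in sizes.values()):
            errors.append("expression.group_sizes: each group needs >= 2 samples")
        eff = expr.get("effect_fraction", 0.39)
        if not 0 <= eff < 1:
            errors.append("expression.effect_fraction: must be in [0, 1)")
    if "copy_number" in stages:
        cn = cfg.get("copy_number", {})
        for key in ("mean_mt_depth", "mean_nuc_depth"):
            if cn.get(key, 1000) <= 0:
                errors.append(f"copy_number.{key}: must be > 0")
        tf = cn.get("tumour_fraction", 0.8)
        if not 0 < tf <= 1:
            errors.append("copy_number.tumour_fraction: must be in (0, 1]")
    if "simulate" not in stages:
        for s, need in (("assign", "inputs.variants"),
                        ("detect", "inputs.tree")):
            if s in stages and not cfg.get("inputs", {}).get(
                    need.split(".")[1]):
                errors.append(f"stage {s!r} requires {need} when not simulating")
    if "mutation_rate" in sim and sim["mutation_rate"] < 0:
        errors.append("simulate.mutation_rate: must be >= 0")
    return errors


def _simulation_config(cfg: dict[str, Any]) -> SimulationConfig:
    sim = dict(cfg.get("simulate", {}))
    het = sim.pop("heteroplasmy_fractions", None)
    if het is not None:
        sim["heteroplasmy_fractions"] = {int(k): float(v)
                                         for k, v in het.items()}
    sim.setdefault("seed", cfg.get("seed", 0))
    return SimulationConfig(**sim)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def label_tumours(cohort: Cohort) -> tuple[dict[str, str], dict[str, dict]]:
    """Per-tumour major haplotype label and haplotype-fraction estimates."""
    profiles = ref.builtin_profiles()
    labels: dict[str, str] = {}
    fractions: dict[str, dict] = {}
    for tumour in cohort.variants.samples():
        vafs = cohort.variants.vafs_of(tumour)
        fr = estimate_haplotype_fractions(vafs, profiles)
        if not fr:
            name, _, _ = assign_haplotype(set(vafs), profiles)
            fr = {name: 1.0}
        fractions[tumour] = fr
        labels[tumour] = max(sorted(fr), key=lambda h: fr[h])
    return labels, fractions


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None,
                 seed: int | None = None) -> Path:
    """Execute the configured stages; returns the report directory."""
    errors = validate_config(config_path)
    if errors:
        raise ConfigError("; ".join(errors))
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", ALL_STAGES)
    out = Path(out_dir or cfg.get("out_dir", "mthijack_report"))
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    outputs: dict[str, Path] = {}
    timers: dict[str, float] = {}

    sim_config = _simulation_config(cfg)
    t0 = time.perf_counter()
    cohort = simulate_ctvt_cohort(sim_config)
    timers["simulate"] = time.perf_counter() - t0
    if "simulate" in stages:
        bundle = write_fixture_bundle(cohort, out / "cohort")
        outputs.update({f"cohort/{k}": v for k, v in bundle.items()
                        if v.is_file()})

    profiles = ref.builtin_profiles()
    labels, fractions = label_tumours(cohort)
    host_haplotype = dict(zip(cohort.truth.tumours["tumour"],
                              cohort.truth.tumours["host_haplotype"]))
    locations = dict(zip(cohort.truth.tumours["tumour"],
                         cohort.truth.tumours["location"]))

    events: list[HTEvent] = []
    if "detect" in stages or "enrich" in stages or "date" in stages:
        t0 = time.perf_counter()
        events = detect_ht_events(cohort.nuclear_tree, labels)
        for event in events:
            event.replaced_haplotype = infer_replaced_haplotype(
                event, cohort.nuclear_tree, labels)
        event_of = {m: e for e in events for m in e.members}
        for tumour, fr in fractions.items():
            if len(fr) < 2:
                continue
            call = call_heteroplasmy(fr, host_haplotype[tumour],
                                     tumour_id=tumour)
            if not call.is_heteroplasmic:
                continue
            own = event_of[tumour]
            own.heteroplasmy[tumour] = fr.get(own.donor_haplotype, 1.0)
            # a minor haplotype not explained by the host, the clade donor
            # or the clade's incumbent is an additional heteroplasmic
            # transfer into this tumour
            for hap, f in fr.items():
                if hap not in (own.donor_haplotype, host_haplotype[tumour],
                               own.replaced_haplotype) and f > 0.10:
                    events.append(HTEvent(
                        event_id=f"HT{len(events) + 1}",
                        donor_haplotype=hap, members=(tumour,),
                        replaced_haplotype=own.donor_haplotype,
                        heteroplasmy={tumour: f}))
        for event in events:
            if not event.location or event.location == "ambiguous":
                event.location = infer_event_location(event, locations,
                                                      cohort.nuclear_tree)
            somatic, fixed = classify_group_variants(
                event, cohort.variants, profiles[event.donor_haplotype])
            event.somatic_counts = {m: len(v) for m, v in somatic.items()}
            event.fixed_unknown = fixed
        timers["detect"] = time.perf_counter() - t0
        if "detect" in stages:
            rows = [{
                "event_id": e.event_id,
                "donor_haplotype": e.donor_haplotype,
                "replaced_haplotype": e.replaced_haplotype,
                "n_tumours": e.n_tumours,
                "pct_heteroplasmy": round(
                    100 * float(np.mean(list(e.heteroplasmy.values()))), 1),
                "location": e.location,
                "mean_somatic": round(float(np.mean(
                    list(e.somatic_counts.values()))), 3)
                if e.somatic_counts else float("nan"),
            } for e in events]
            outputs["events"] = out / "events.tsv"
            pd.DataFrame(rows).to_csv(outputs["events"], sep="\t", index=False)

    if "enrich" in stages:
        t0 = time.perf_counter()
        enrich_cfg = cfg.get("enrich", {})
        target = enrich_cfg.get("target_haplotype", "A1d1a")
        observed = sum(1 for e in events if e.donor_haplotype == target)
        result = enrichment_test(
            sim_config.haplotype_freqs, n_events=len(events),
            observed_count=observed, target_haplotype=target,
            replicates=int(enrich_cfg.get("replicates", 10000)),
            seed=int(enrich_cfg.get("seed", 76)))
        outputs["enrichment"] = out / "enrichment.json"
        outputs["enrichment"].write_text(json.dumps(
            result.__dict__, indent=2, sort_keys=True) + "\n")
        timers["enrich"] = time.perf_counter() - t0

    if "date" in stages:
        t0 = time.perf_counter()
        anchor = cfg.get("rate_anchor", DEFAULT_RATE_ANCHOR)
        rate = calibrate_rate(anchor["mean_mutations"],
                              anchor["divergence_years"],
                              tuple(anchor["divergence_interval"]))
        rows = []
        for e in events:
            if not e.somatic_counts:
                continue
            mean_count = float(np.mean(list(e.somatic_counts.values())))
            point, (lo, hi) = date_ht_event(mean_count, rate)
            rows.append({"event_id": e.event_id, "donor": e.donor_haplotype,
                         "mean_somatic": round(mean_count, 3),
                         "age_years": round(point, 2),
                         "age_low": round(lo, 2), "age_high": round(hi, 2)})
        outputs["dating"] = out / "dating.tsv"
        pd.DataFrame(rows).to_csv(outputs["dating"], sep="\t", index=False)
        timers["date"] = time.perf_counter() - t0

    if "copy_number" in stages:
        t0 = time.perf_counter()
        cn_cfg = cfg.get("copy_number", {})
        support = simulate_read_support(
            cohort.variants,
            mean_mt_depth=cn_cfg.get("mean_mt_depth", 3000.0),
            mean_nuc_depth=cn_cfg.get("mean_nuc_depth", 100.0),
            tumour_fraction=cn_cfg.get("tumour_fraction", 0.8),
            seed=seed + 11)
        rows = []
        for r in support.coverage.itertuples(index=False):
            obs = support.observed_mt_vafs
            mt_vafs = obs.loc[obs["sample"] == r.sample, "vaf"]
            try:
                nuc_frac = estimate_nuclear_tumour_fraction(
                    support.nuclear_somatic_vafs[r.sample])
                mt_frac = estimate_mt_tumour_fraction(mt_vafs.to_numpy())
                cn = mtdna_copy_number(
                    CoverageSummary(r.sample, r.mt_coverage, r.nuclear_coverage),
                    mt_frac, nuc_frac)
            except ValueError as exc:
                warnings.append(f"copy number skipped for {r.sample}: {exc}")
                continue
            rows.append({"sample": r.sample, "haplotype": labels[r.sample],
                         "copy_number": round(cn, 2)})
        cn_df = pd.DataFrame(rows)
        outputs["copy_number"] = out / "copy_number.tsv"
        cn_df.to_csv(outputs["copy_number"], sep="\t", index=False)
        in_target = cn_df["haplotype"] == "A1d1a"
        if in_target.sum() >= 2 and (~in_target).sum() >= 2:
            t, p = compare_groups_ttest(cn_df.loc[in_target, "copy_number"],
                                        cn_df.loc[~in_target, "copy_number"])
            outputs["copy_number_test"] = out / "copy_number_test.json"
            outputs["copy_number_test"].write_text(json.dumps(
                {"t": t, "p": p, "n_a1d1a": int(in_target.sum()),
                 "n_other": int((~in_target).sum())}, indent=2) + "\n")
        timers["copy_number"] = time.perf_counter() - t0

    if "phase" in stages:
        t0 = time.perf_counter()
        sim = simulate_recombinant_reads(seed=seed + 23)
        phasing = phase_long_reads(sim.reads)
        hap_sets = [haplotype_variant_set(h, sim.donor_site_variants)
                    for h in phasing.haplotypes]
        universal = fixed_variants(
            hap_sets, set(v for _, v in sim.donor_site_variants.values()))
        rows = [{"haplotype": f"H{i + 1}",
                 "frequency": round(h.frequency, 4),
                 "n_reads": h.n_reads, "low_level": h.low_level}
                for i, h in enumerate(phasing.haplotypes)]
        outputs["phasing"] = out / "phasing.tsv"
        pd.DataFrame(rows).to_csv(outputs["phasing"], sep="\t", index=False)
        outputs["phasing_fixed"] = out / "phasing_fixed_variants.json"
        outputs["phasing_fixed"].write_text(json.dumps(
            {"fixed_donor_variants": sorted(str(v) for v in universal),
             "unassigned_fraction": phasing.unassigned_fraction},
            indent=2) + "\n")
        timers["phase"] = time.perf_counter() - t0

    if "expression" in stages:
        t0 = time.perf_counter()
        expr_cfg = cfg.get("expression", {})
        cm = simulate_expression_counts(
            group_sizes=expr_cfg.get("group_sizes",
                                     {"A1d1a": 15, "CTVT_HT": 15}),
            affected_group=expr_cfg.get("affected_group", "A1d1a"),
            effect_fraction=expr_cfg.get("effect_fraction", 0.39),
            dispersion=expr_cfg.get("dispersion", 0.15),
            seed=seed + 37)
        log_ab = normalised_log_abundance(cm.counts)
        corrected = batch_correct(log_ab, cm.samples["batch"],
                                  cm.samples["group"])
        groups = list(expr_cfg.get("group_sizes",
                                   {"A1d1a": 15, "CTVT_HT": 15}))
        pct, p = group_abundance_change(corrected, cm.samples, groups[0],
                                        groups[1], cm.gene_classes)
        restricted = [g for g in cm.gene_classes.index
                      if cm.gene_classes[g] in ("mtDNA", "nuclear")]
        per_gene = per_gene_differential(
            corrected, cm.samples, groups[0], groups[1], restricted)
        outputs["expression"] = out / "expression.json"
        outputs["expression"].write_text(json.dumps({
            "pct_decrease_mtdna": round(pct, 3),
            "mann_whitney_p": p,
            "n_genes_q_lt_0.05": int(
                (per_gene.loc[cm.gene_classes == "mtDNA", "q"] < 0.05).sum()),
        }, indent=2) + "\n")
        outputs["expression_per_gene"] = out / "expression_per_gene.tsv"
        per_gene.to_csv(outputs["expression_per_gene"], sep="\t")
        timers["expression"] = time.perf_counter() - t0

    manifest = {
        "config": cfg,
        "seed": seed,
        "stages": [s for s in ALL_STAGES if s in stages],
        "outputs": {k: {"path": str(v.relative_to(out)), "sha256": _sha256(v)}
                    for k, v in sorted(outputs.items())},
        "warnings": warnings,
        "stage_seconds": {k: round(v, 3) for k, v in timers.items()},
        "generated_unix_time": time.time(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
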