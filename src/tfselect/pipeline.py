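"""End-to-end orchestration: windows -> predictions -> controls -> statistics.

The full procedure, per cancer type and motif:

1. extract deduplicated mutation-centered windows in regulatory regions;
2. classify affinity changes for cancer windows and for two control pools
   (shuffled flanks; genomic loci matched on the central trinucleotide);
3. per motif and direction, equalize the control mutation-context
   distribution to the cancer one, impute deficits uniformly, and build the
   2x2 event table;
4. Fisher exact tests, Benjamini-Hochberg FDR per (cancer, control,
   direction) family, selection magnitudes, and the both-controls
   consistency call;
5. optionally, the simplified overlap test and positional density profiles.

Every random step draws from one seeded generator recorded in the run
manifest, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import affinity, stats
from .controls import GenomicSampler, equalize_contexts, make_shuffle_controls
from .density import PositionalProfile, build_profile
from .overlap import overlap_tally
from .pwm import PositionWeightMatrix, load_matrix_dir
from .stats import (MotifSelectionResult, build_table, call_selection,
                    evaluate_family, fisher_two_sided, results_to_table)
from .windows import (MutationWindow, RegionSet, dedup_windows,
                      extract_windows, load_mutations, select_regulatory)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables; the statistical defaults are the published ones
    (site P-value 0.0005, 4-fold ratio, 10 bp hit distance, +-50 bp windows,
    FDR alpha 0.05)."""

    # inputs (unused when running on an in-memory synthetic study)
    mutations: Optional[str] = None
    mutations_format: str = "tsv"
    genome: Optional[str] = None
    promoter_bed: Optional[str] = None
    intron_bed: Optional[str] = None
    coding_bed: Optional[str] = None
    dnase_bed: Optional[str] = None
    motif_dir: Optional[str] = None
    motif_format: str = "counts"
    # parameters
    p_site: float = 0.0005
    fold: float = 4.0
    max_dist: int = 10
    half_window: int = 50
    control_multiplier: float = 5.0
    shuffle_per_mutation: int = 5
    genomic_per_mutation: int = 5
    fdr_alpha: float = 0.05
    min_eligible: int = 100
    seed: int = 1
    cancer_types: Optional[Sequence[str]] = None
    dnase_restrict: bool = False
    run_overlap: bool = True
    run_density: bool = False
    emit_calls: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cancer_types"] = list(self.cancer_types) if self.cancer_types else None
        return d


@dataclass
class CancerAnalysis:
    """Everything computed for one cancer type."""

    cancer_type: str
    results: list[MotifSelectionResult] = field(default_factory=list)
    calls: dict = field(default_factory=dict)            # (motif, direction) -> call
    overlap_results: list[MotifSelectionResult] = field(default_factory=list)
    equalization: list[dict] = field(default_factory=list)
    profiles: list[PositionalProfile] = field(default_factory=list)
    counts: dict = field(default_factory=dict)           # stage bookkeeping

    def result_for(self, motif: str, direction: str, control: str
                   ) -> Optional[MotifSelectionResult]:
        for r in self.results:
            if (r.motif, r.direction, r.control) == (motif, direction, control):
                return r
        return None

    def magnitude(self, motif: str, direction: str, control: str = "genomic") -> float:
        r = self.result_for(motif, direction, control)
        return r.magnitude if r is not None else float("nan")


def analyze_windows(test_windows: Sequence[MutationWindow],
                    pwms: Sequence[PositionWeightMatrix],
                    sampler: GenomicSampler, config: RunConfig,
                    rng: np.random.Generator, cancer_type: str = ""
                    ) -> CancerAnalysis:
    """Run steps 2-5 on an extracted, deduplicated window set."""
    out = CancerAnalysis(cancer_type=cancer_type)
    out.counts["windows"] = len(test_windows)
    if not test_windows:
        return out

    # control pools are motif-independent: build once, classify per motif
    shuffle_pool = []
    for w in test_windows:
        shuffle_pool.extend(make_shuffle_controls(w, config.shuffle_per_mutation, rng))
    ctx_counts: dict = {}
    for w in test_windows:
        ctx_counts[w.context] = ctx_counts.get(w.context, 0) + 1
    genomic_pool = []
    for ctx in sorted(ctx_counts, key=str):
        genomic_pool.extend(
            sampler.sample(ctx, config.genomic_per_mutation * ctx_counts[ctx], rng))
    out.counts["shuffle_pool"] = len(shuffle_pool)
    out.counts["genomic_pool"] = len(genomic_pool)

    test_codes = affinity.encode_window_pair(test_windows)
    pools = {"shuffle": (shuffle_pool, affinity.encode_window_pair(shuffle_pool)
                         if shuffle_pool else None),
             "genomic": (genomic_pool, affinity.encode_window_pair(genomic_pool)
                         if genomic_pool else None)}

    by_family: dict = {}  # (control, direction) -> list of results, FDR family
    for pwm in pwms:
        test_calls = _classify_codes(test_windows, test_codes, pwm, config)
        test_tally = affinity.tally(test_calls)
        out.counts[f"{pwm.name}/loss_eligible"] = test_tally["n_loss_eligible"]
        out.counts[f"{pwm.name}/gain_eligible"] = test_tally["n_gain_eligible"]
        for control_name, (pool, pool_codes) in pools.items():
            pool_calls = (_classify_codes(pool, pool_codes, pwm, config)
                          if pool else [])
            for direction, flag in (("loss", "eligible_for_loss"),
                                    ("gain", "eligible_for_gain")):
                test_elig = [c for c in test_calls if getattr(c, flag)]
                ctrl_elig = [c for c in pool_calls if getattr(c, flag)]
                # request no more context-matched windows than the pool holds
                n_target = min(int(round(config.control_multiplier * len(test_elig))),
                               len(ctrl_elig))
                sampled, report = equalize_contexts(
                    test_elig, ctrl_elig, rng, n_target=n_target, motif=pwm.name)
                ctrl_tally = affinity.tally(sampled) if sampled else {
                    "n_loss_eligible": 0, "n_loss_events": 0,
                    "n_gain_eligible": 0, "n_gain_events": 0}
                table = build_table(test_tally, ctrl_tally,
                                    report.total_deficit, direction)
                res = MotifSelectionResult(
                    motif=pwm.name, cancer_type=cancer_type, control=control_name,
                    direction=direction, table=table, deficit=report.total_deficit,
                    p=fisher_two_sided(table))
                by_family.setdefault((control_name, direction), []).append(res)
                out.results.append(res)
                out.equalization.append({
                    "motif": pwm.name, "control": control_name,
                    "direction": direction, "target": report.total_target,
                    "sampled": report.total_sampled,
                    "deficit": report.total_deficit,
                    "match_fraction": report.match_fraction})
            if config.run_overlap:
                _overlap_analysis(out, pwm, test_calls, pool_calls, control_name,
                                  config, rng, cancer_type)
        if config.run_density:
            out.profiles.append(build_profile(test_windows, pwm, "cancer",
                                              config.p_site, config.max_dist))
            for control_name, (pool, _) in pools.items():
                if pool:
                    out.profiles.append(build_profile(pool, pwm, control_name,
                                                      config.p_site, config.max_dist))

    for family in by_family.values():
        evaluate_family(family, config.fdr_alpha, config.min_eligible)
    if config.run_overlap:
        for control_name in pools:
            fam = [r for r in out.overlap_results if r.control == control_name]
            evaluate_family(fam, config.fdr_alpha, config.min_eligible)
    for pwm in pwms:
        for direction in ("loss", "gain"):
            out.calls[(pwm.name, direction)] = call_selection(
                out.result_for(pwm.name, direction, "shuffle"),
                out.result_for(pwm.name, direction, "genomic"),
                config.fdr_alpha)
        if config.run_overlap:
            shuffle_r = next((r for r in out.overlap_results
                              if r.motif == pwm.name and r.control == "shuffle"), None)
            genomic_r = next((r for r in out.overlap_results
                              if r.motif == pwm.name and r.control == "genomic"), None)
            if shuffle_r and genomic_r:
                out.calls[(pwm.name, "overlap")] = call_selection(
                    shuffle_r, genomic_r, config.fdr_alpha)
    return out


def _classify_codes(windows, codes_pair, pwm, config):
    germ, mut = codes_pair
    hits_g = pwm.scan_batch(germ, max_dist=config.max_dist)
    hits_m = pwm.scan_batch(mut, max_dist=config.max_dist)
    calls = []
    for i, w in enumerate(windows):
        p_g = float(hits_g.pvalue[i])
        p_m = float(hits_m.pvalue[i])
        call, el, eg = affinity._decide(p_g, p_m, config.p_site, config.fold)
        calls.append(affinity.AffinityCall(pwm.name, w, p_g, p_m, p_m / p_g,
                                           call, el, eg))
    return calls


def _overlap_analysis(out, pwm, test_calls, pool_calls, control_name, config,
                      rng, cancer_type):
    """Simplified overlap test; eligibility equals the loss-direction one."""
    test_elig = [c for c in test_calls if c.eligible_for_loss]
    ctrl_elig = [c for c in pool_calls if c.eligible_for_loss]
    n_target = min(int(round(config.control_multiplier * len(test_elig))),
                   len(ctrl_elig))
    sampled, report = equalize_contexts(test_elig, ctrl_elig, rng,
                                        n_target=n_target, motif=pwm.name)
    t_tally = overlap_tally([c.window for c in test_elig], pwm,
                            config.p_site, config.max_dist)
    c_tally = overlap_tally([c.window for c in sampled], pwm,
                            config.p_site, config.max_dist)
    table = build_table(t_tally, c_tally, report.total_deficit, "overlap")
    out.overlap_results.append(MotifSelectionResult(
        motif=pwm.name, cancer_type=cancer_type, control=control_name,
        direction="overlap", table=table, deficit=report.total_deficit,
        p=fisher_two_sided(table)))


# -- file-based entry point -----------------------------------------------------


def run(config: RunConfig, out_dir) -> Path:
    """Execute the configured study and write TSV outputs plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in ("mutations", "genome", "promoter_bed", "intron_bed", "motif_dir"):
        if getattr(config, key) is None:
            raise ValueError(f"configuration is missing required input {key!r}")

    pwms = load_matrix_dir(config.motif_dir, format=config.motif_format)
    promoters = RegionSet.from_bed(config.promoter_bed, "promoter")
    introns = RegionSet.from_bed(config.intron_bed, "intron")
    coding = (RegionSet.from_bed(config.coding_bed, "coding")
              if config.coding_bed else None)
    dnase = (RegionSet.from_bed(config.dnase_bed, "dnase")
             if config.dnase_bed else None)

    records = load_mutations(config.mutations, config.mutations_format)
    kept = select_regulatory(records, promoters, introns, coding,
                             dnase if config.dnase_restrict else None)
    by_cancer: dict[str, list] = {}
    for mut in kept:
        by_cancer.setdefault(mut.cancer_type, []).append(mut)
    cancers = list(config.cancer_types) if config.cancer_types else sorted(by_cancer)

    seeds = np.random.SeedSequence(config.seed).spawn(len(cancers))
    all_windows: list[MutationWindow] = []
    analyses = []
    for cancer, seed_seq in zip(cancers, seeds):
        muts = by_cancer.get(cancer, [])
        windows = dedup_windows(extract_windows(muts, config.genome,
                                                config.half_window))
        all_windows.append((cancer, windows, seed_seq))
    # exclusion set spans every cancer window so controls never overlap test data
    flat_windows = [w for _, ws, _ in all_windows for w in ws]
    region_sets = [promoters, introns] if dnase is None or not config.dnase_restrict \
        else [dnase]
    sampler = GenomicSampler(config.genome, region_sets, exclusion=flat_windows,
                             half=config.half_window)
    for cancer, windows, seed_seq in all_windows:
        rng = np.random.default_rng(seed_seq)
        analysis = analyze_windows(windows, pwms, sampler, config, rng, cancer)
        analysis.counts["mutations_in"] = len(by_cancer.get(cancer, []))
        analyses.append(analysis)
        _write_analysis(analysis, out_dir)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "cancers": cancers,
        "versions": _versions(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir


def _write_analysis(analysis: CancerAnalysis, out_dir: Path) -> None:
    tag = analysis.cancer_type or "all"
    results_to_table(analysis.results, analysis.calls).to_csv(
        out_dir / f"{tag}.selection.tsv", sep="\t", index=False)
    if analysis.overlap_results:
        results_to_table(analysis.overlap_results, analysis.calls).to_csv(
            out_dir / f"{tag}.overlap.tsv", sep="\t", index=False)
    pd.DataFrame(analysis.equalization).to_csv(
        out_dir / f"{tag}.equalization.tsv", sep="\t", index=False)
    if analysis.profiles:
        pd.concat([p.to_frame() for p in analysis.profiles]).to_csv(
            out_dir / f"{tag}.profiles.tsv", sep="\t", index=False)
    with open(out_dir / f"{tag}.counts.json", "w") as fh:
        json.dump(analysis.counts, fh, indent=2, sort_keys=True)


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"tfselect": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


def run_demo(out_dir, seed: int = 1, config: Optional[RunConfig] = None,
             study=None) -> tuple:
    """Simulate the demo study and run the full pipeline on it in memory."""
    from .simulate import simulate_study

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if study is None:
        study = simulate_study(seed=seed)
    run_config = config or RunConfig(seed=seed)
    windows = dedup_windows(extract_windows(study.mutations,
                                            study.genome.fasta_like,
                                            run_config.half_window))
    sampler = GenomicSampler(study.genome.fasta_like,
                             [study.genome.regions["promoter"],
                              study.genome.regions["intron"]],
                             exclusion=windows, half=run_config.half_window)
    rng = np.random.default_rng(np.random.SeedSequence(run_config.seed).spawn(1)[0])
    pwms = [pm.pwm for pm in study.config.motifs]
    analysis = analyze_windows(windows, pwms, sampler, run_config, rng,
                               study.config.cancer_type)
    _write_analysis(analysis, out_dir)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"config": run_config.to_dict(), "seed": run_config.seed,
                   "versions": _versions()}, fh, indent=2, sort_keys=True)
    return study, analysis
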