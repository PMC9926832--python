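"""End-to-end pipeline orchestration: simulate -> call -> impute -> qc ->
gwas -> clump, with per-stage logging, count conservation and a manifest
that makes runs reproducible from (config, seed) alone."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assoc, loci as loci_mod, popcall
from .benchmark import bonferroni_threshold, fit_accuracy_model, run_grid
from .config import PipelineConfig
from .impute import GenotypePosterior, HmmParams, SiteInfo, Sites, impute_region
from .qc_filters import apply_filters, qc_table
from .synthetic_cohort import (
    CohortTruth,
    HaplotypePanel,
    PhenotypeModel,
    ReadPileup,
    default_error_profile,
    generate_panel,
    make_clinical_covariates,
    sample_cohort,
    simulate_phenotype,
    simulate_pileups,
)

log = logging.getLogger("ulcgwas")


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    seconds: float


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = ""
    stages: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def summary(self) -> str:
        lines = [f"config {self.config_hash} seed {self.seed} ulcgwas {self.version}"]
        for s in self.stages:
            lines.append(f"  {s.name}: {s.n_in} -> {s.n_out} ({s.seconds:.1f}s)")
        for k, v in self.counts.items():
            lines.append(f"  {k} = {v}")
        if self.failed_stage:
            lines.append(f"  FAILED at {self.failed_stage}")
        return "\n".join(lines)


@dataclass
class PipelineResult:
    manifest: RunManifest
    panel: HaplotypePanel | None = None
    cohort: CohortTruth | None = None
    pileup: ReadPileup | None = None
    phenotype: np.ndarray | None = None
    clinical: np.ndarray | None = None
    calls: list | None = None
    kept_sites: np.ndarray | None = None
    sites: Sites | None = None
    posterior: GenotypePosterior | None = None
    site_info: SiteInfo | None = None
    qc_records: list | None = None
    qc_survivors: np.ndarray | None = None
    scan: list | None = None
    effects: list | None = None
    gc: assoc.GcReport | None = None
    sig_sites: list | None = None
    loci: list | None = None
    causal_sites: np.ndarray | None = None
    p_threshold: float | None = None


def _seed(base: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(base), int(tag)]).generate_state(1)[0] % 2**31)


def _stage(manifest: RunManifest, name: str, n_in: int, n_out: int, t0: float) -> None:
    rec = StageRecord(name, n_in, n_out, time.time() - t0)
    manifest.stages.append(rec)
    log.info("stage %-8s %6d -> %6d  %.1fs", name, n_in, n_out, rec.seconds)


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Run the full chain on a synthetic cohort; deterministic per seed."""
    from . import __version__

    manifest = RunManifest(config.config_hash(), config.seed, version=__version__)
    res = PipelineResult(manifest=manifest)
    seed = config.seed

    try:
        # ---- simulate -----------------------------------------------------
        t0 = time.time()
        pc = config.panel
        panel = generate_panel(
            pc.n_hap, pc.n_sites, pc.region_length, pc.recomb_rate,
            ("uniform", pc.af_low, pc.af_high), seed=_seed(seed, 1),
            n_founders=pc.n_founders, chrom=pc.chrom, n_blocks=pc.n_blocks,
        )
        cohort = sample_cohort(
            panel, config.cohort.n_samples, config.cohort.sibs_per_family,
            seed=_seed(seed, 2),
        )
        profile = default_error_profile(config.pileup.base_error)
        pileup = simulate_pileups(
            cohort, panel, config.pileup.coverage, profile, seed=_seed(seed, 3)
        )
        clinical = make_clinical_covariates(cohort.n_samples, seed=_seed(seed, 4))

        gw = config.gwas
        true_maf = np.minimum(cohort.true_af, 1 - cohort.true_af)
        causal = np.argsort(np.abs(true_maf - gw.causal_maf))[: gw.n_causal]
        betas = np.full(gw.n_causal, gw.causal_beta)
        explained = float(
            (betas**2 * 2 * cohort.true_af[causal] * (1 - cohort.true_af[causal])).sum()
            + 8 * gw.covariate_effect**2
            + 2 * gw.batch_shift**2
        )
        noise_sd = float(np.sqrt(max(0.05, 1.0 - explained)))
        model = PhenotypeModel(
            causal_sites=causal,
            betas=betas,
            covariate_effects=np.full(8, gw.covariate_effect),
            wga_effects=np.linspace(-1, 1, 3) * gw.batch_shift,
            platform_effects=np.linspace(-1, 1, 4) * gw.batch_shift,
            noise_sd=noise_sd,
        )
        phenotype = simulate_phenotype(cohort, model, clinical, seed=_seed(seed, 5))
        res.panel, res.cohort, res.pileup = panel, cohort, pileup
        res.phenotype, res.clinical, res.causal_sites = phenotype, clinical, causal
        _stage(manifest, "simulate", pc.n_sites, pileup.n_reads, t0)

        # ---- call ---------------------------------------------------------
        t0 = time.time()
        calls = popcall.call_sites(
            pileup, panel.chrom, panel.positions, panel.ref, alpha=config.call.alpha
        )
        if config.call.exclusion_bed:
            from .io import read_bed

            calls = popcall.apply_region_filters(calls, read_bed(config.call.exclusion_bed))
        kept = np.array(
            [
                i
                for i, c in enumerate(calls)
                if c.status == popcall.PASS
                and min(c.f_hat, 1 - c.f_hat) >= config.call.maf_min
            ],
            dtype=np.int64,
        )
        res.calls, res.kept_sites = calls, kept
        _stage(manifest, "call", panel.n_sites, len(kept), t0)
        if len(kept) == 0:
            raise RuntimeError("no PASS sites after population calling")

        # ---- impute -------------------------------------------------------
        t0 = time.time()
        ic = config.impute
        params = HmmParams(
            K=ic.K, n_gen=ic.n_gen, grid_size=ic.grid_size,
            window_size=ic.window_size, window_overlap=ic.window_overlap,
            n_em_iters=ic.n_em_iters, recomb_rate_bp=ic.recomb_rate_bp,
            seed=_seed(seed, 6),
        )
        sites = Sites(panel.chrom, panel.positions[kept], panel.ref[kept], panel.alt[kept])
        f_hat = np.array([calls[i].f_hat for i in kept])
        sub_pileup = pileup.subset_sites(kept)
        post, site_info, _ = impute_region(sub_pileup, sites, params, af_init=f_hat)
        res.sites, res.posterior, res.site_info = sites, post, site_info
        _stage(manifest, "impute", len(kept), len(kept), t0)

        # ---- qc -----------------------------------------------------------
        t0 = time.time()
        rng = np.random.default_rng(_seed(seed, 7))
        known = rng.random(len(kept)) < config.qc.known_fraction
        records = qc_table(post, known)
        survivors = apply_filters(
            records,
            info_min=config.qc.info_min,
            hwe_min=config.qc.hwe_min,
            maf_min=config.qc.maf_min,
            require_known=config.qc.require_known,
        )
        res.qc_records, res.qc_survivors = records, survivors
        _stage(manifest, "qc", len(kept), len(survivors), t0)
        if len(survivors) == 0:
            raise RuntimeError("no sites survive QC filters")

        # ---- gwas ---------------------------------------------------------
        t0 = time.time()
        D = post.dosage
        pcs = assoc.compute_pcs(D, n_pcs=gw.n_pcs, maf_min=0.05)
        X = assoc.build_covariates(cohort.n_samples, pcs, clinical)
        y = assoc.standardize_phenotype(phenotype)
        null = assoc.fit_null(y, X)
        scan = assoc.score_scan(
            D[:, survivors], null, post.gp[:, survivors, :],
            min_high=gw.min_high, high_cutoff=gw.high_cutoff, site_ids=survivors,
        )
        tested = [r for r in scan if r.tested_flag]
        p_thresh = bonferroni_threshold(max(len(tested), 1), gw.bonferroni_alpha)
        sig = [r for r in tested if r.p_value <= p_thresh]
        effects = []
        for r in sig:
            e = assoc.effect_size(D[:, r.site], y, X)
            e.site = r.site
            effects.append(e)
        gc = assoc.genomic_control(np.array([r.chi2 for r in tested]))
        res.scan, res.effects, res.gc = scan, effects, gc
        res.sig_sites, res.p_threshold = sig, p_thresh
        _stage(manifest, "gwas", len(survivors), len(sig), t0)

        # ---- clump --------------------------------------------------------
        t0 = time.time()
        tested_ids = np.array([r.site for r in tested], dtype=np.int64)
        pvals = np.full(len(kept), 1.0)
        for r in tested:
            pvals[r.site] = r.p_value
        ld = loci_mod.ld_matrix(D[:, tested_ids])
        # re-index LD to the kept-site universe for the tested subset
        full_ld = np.full((len(kept), len(kept)), np.nan)
        full_ld[np.ix_(tested_ids, tested_ids)] = ld
        lc = config.loci
        independents = loci_mod.find_independent(
            pvals, sites.positions, full_ld, p_thresh, lc.r2_indep
        )
        leads = loci_mod.find_leads(
            independents, pvals, sites.positions, full_ld, lc.r2_lead
        )
        cands = loci_mod.candidate_snps(
            independents, pvals, np.nan_to_num(full_ld, nan=0.0), lc.r2_cand, lc.p_cand
        )
        risk_loci = loci_mod.define_loci(
            leads, cands, independents, pvals, sites.positions,
            chrom=panel.chrom, merge_dist=lc.merge_dist,
        )
        res.loci = risk_loci
        _stage(manifest, "clump", len(sig), len(risk_loci), t0)

        manifest.counts.update(
            n_sites_panel=panel.n_sites,
            n_called_pass=len(kept),
            n_qc_pass=len(survivors),
            n_tested=len(tested),
            n_significant=len(sig),
            n_loci=len(risk_loci),
            p_threshold=p_thresh,
            lambda_gc=gc.lambda_gc,
        )
    except Exception:
        manifest.failed_stage = manifest.stages[-1].name if manifest.stages else "simulate"
        raise

    if outdir:
        _write_outputs(Path(outdir), config, res)
    return res


def _write_outputs(outdir: Path, config: PipelineConfig, res: PipelineResult) -> None:
    from . import io as io_mod

    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    (outdir / "manifest.txt").write_text(res.manifest.summary() + "\n")
    if res.calls is not None:
        io_mod.write_calls_vcf(outdir / "calls.vcf", res.calls)
    if res.posterior is not None:
        io_mod.write_posteriors_vcf(
            outdir / "imputed.vcf", res.sites, res.posterior, res.site_info
        )
        io_mod.qc_table_frame(
            res.sites, res.qc_records, res.site_info.est_af, res.qc_survivors
        ).to_csv(outdir / "qc.tsv", sep="\t", index=False)
    if res.scan is not None:
        io_mod.sumstats_frame(res.sites, res.scan, res.effects, res.site_info).to_csv(
            outdir / "sumstats.tsv", sep="\t", index=False
        )
        import pandas as pd

        from .assoc import qq_data

        pvals = np.array([r.p_value for r in res.scan if r.tested_flag])
        if len(pvals):
            pd.DataFrame(
                qq_data(pvals), columns=["EXPECTED_NLOG10P", "OBSERVED_NLOG10P"]
            ).to_csv(outdir / "qq.tsv", sep="\t", index=False)
    if res.loci is not None:
        io_mod.loci_frame(res.loci).to_csv(outdir / "loci.tsv", sep="\t", index=False)


def run_benchmark(config: PipelineConfig):
    """Benchmark mode: accuracy grid + accuracy-model fit on one panel."""
    pc = config.benchmark.panel
    panel = generate_panel(
        pc.n_hap, pc.n_sites, pc.region_length, pc.recomb_rate,
        ("uniform", pc.af_low, pc.af_high), seed=_seed(config.seed, 1),
        n_founders=pc.n_founders, chrom=pc.chrom, n_blocks=pc.n_blocks,
    )
    ic = config.impute
    params = HmmParams(
        K=ic.K, n_gen=ic.n_gen, grid_size=ic.grid_size,
        window_size=ic.window_size, window_overlap=ic.window_overlap,
        n_em_iters=ic.n_em_iters, recomb_rate_bp=ic.recomb_rate_bp,
        seed=_seed(config.seed, 6),
    )
    bc = config.benchmark
    grid = run_grid(
        panel, list(bc.coverages), list(bc.sizes), seed=config.seed,
        cohort_coverage=config.pileup.coverage,
        sibs_per_family=config.cohort.sibs_per_family,
        params=params, alpha=config.call.alpha, maf_min=config.call.maf_min,
        base_error=config.pileup.base_error,
    )
    fit = fit_accuracy_model(grid, c_min=bc.c_min, s_min=bc.s_min)
    return grid, fit
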