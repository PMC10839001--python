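"""Config-driven end-to-end runs and publication-shaped reports.

``run_pipeline`` sequences the stages

    phenotypes -> expression -> relationship -> varcomp -> association

for each requested trait and writes: a descriptive-statistics report
(mean/SD/min/max/mean-SD-ratio per trait), a variance-components report
with explicit "Not converged" rows, per-trait association tables sorted
for Manhattan plotting, inflation reports, the Bonferroni/top-20
significance report, and a line-oriented timestamped log recording every
stage's parameters and the counts flowing in and out of every filter.

All randomness flows from the single top-level seed, fanned out to named
substreams (simulation uses the seed itself; the inflation bootstrap uses
an independent child stream).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .association import inflation_factor, moa_scan, moment_test, significance_report
from .expression import cpm, filter_expressed, standardize, tmm_factors
from .phenotypes import apply_qc, derive_adg, descriptive_stats, trait_correlations
from .relationship import build_orm
from .synthetic import SyntheticConfig, simulate_counts, simulate_phenotypes
from .varcomp import design_from_phenotypes, fit_reml

__all__ = ["RunConfig", "run_pipeline"]

TRAITS = ("bw84", "adg35", "adg56", "adg70")


@dataclass
class RunConfig:
    """Validated run configuration; exactly one of real inputs or a
    synthetic block must be present, and unknown keys are rejected."""

    outdir: str = "omictwas_run"
    seed: int = 0
    traits: tuple[str, ...] = TRAITS
    level: str = "gene"
    counts: str | None = None
    annotation: str | None = None
    phenotypes: str | None = None
    synthetic: dict | None = None
    mad_k: float = 3.0
    mad_constant: float = 1.4826
    min_count: int = 2
    min_frac: float = 0.30
    trim_m: float = 0.30
    trim_a: float = 0.05
    moment_bins: int = 2
    n_boot: int = 1000
    alpha: float = 0.05
    top_k: int = 20
    save_matrices: bool = False
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        real = all(x is not None for x in (self.counts, self.annotation, self.phenotypes))
        some_real = any(x is not None for x in (self.counts, self.annotation, self.phenotypes))
        if self.synthetic is not None and some_real:
            raise ValueError("provide either real input paths or a synthetic block, not both")
        if self.synthetic is None and not real:
            raise ValueError(
                "incomplete input: need counts+annotation+phenotypes paths "
                "or a synthetic block"
            )
        if self.synthetic is not None:
            syn_known = {f.name for f in fields(SyntheticConfig)}
            unknown = set(self.synthetic) - syn_known
            if unknown:
                raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
        bad = set(self.traits) - set(TRAITS)
        if bad:
            raise ValueError(f"unknown traits: {sorted(bad)}")

    def synthetic_config(self) -> SyntheticConfig:
        block = dict(self.synthetic or {})
        block.setdefault("seed", self.seed)
        if "growth_curve_params" in block:
            block["growth_curve_params"] = {
                int(k): tuple(v) for k, v in block["growth_curve_params"].items()
            }
        if "season_effects" in block:
            block["season_effects"] = tuple(block["season_effects"])
        return SyntheticConfig(**block)


def _setup_log(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"omictwas.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    logger.propagate = False
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s\t%(levelname)s\t%(message)s"))
    logger.addHandler(handler)
    return logger


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory results and
    writes all report artifacts under ``config.outdir``.

    A failure in one trait's variance-component or association stage is
    recorded (the variance report prints "Not converged") and only that
    trait's downstream stages are skipped.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _setup_log(outdir)
    t0 = time.time()
    log.info("run start: seed=%d level=%s traits=%s", config.seed, config.level,
             ",".join(config.traits))

    # ---- stage: inputs -------------------------------------------------
    if config.synthetic is not None:
        syn = config.synthetic_config()
        counts = simulate_counts(syn)
        pheno = simulate_phenotypes(counts, syn)
        tio.write_counts_tsv(counts, outdir / "counts.tsv")
        tio.write_gtf(counts.feature_meta, outdir / "annotation.gtf")
        tio.write_phenotypes_tsv(pheno, outdir / "phenotypes.tsv")
        log.info("simulate: n=%d genes=%d seed=%d", counts.n_individuals,
                 counts.n_features, syn.seed)
    else:
        counts = tio.read_counts_tsv(config.counts, config.annotation)
        pheno = tio.read_phenotypes_tsv(config.phenotypes)
        log.info("load: counts %dx%d, phenotypes %d rows", counts.n_features,
                 counts.n_individuals, len(pheno))

    # ---- stage: phenotypes --------------------------------------------
    pheno = apply_qc(pheno, k=config.mad_k, c=config.mad_constant)
    pheno = derive_adg(pheno)
    n_fail = int((~pheno["qc_pass"]).sum())
    log.info("phenotype QC: %d in, %d excluded by MAD rule (k=%g, c=%g)",
             len(pheno), n_fail, config.mad_k, config.mad_constant)
    pheno.to_csv(outdir / "qc_report.tsv", sep="\t", index=False, float_format="%.6g")

    kept = pheno[pheno["qc_pass"]].reset_index(drop=True)
    desc = pd.DataFrame(
        [descriptive_stats(kept, t) for t in config.traits if t in kept.columns]
    )
    desc.to_csv(outdir / "descriptives.tsv", sep="\t", index=False)
    corr = trait_correlations(kept)
    corr.to_csv(outdir / "trait_correlations.tsv", sep="\t", index_label="trait")
    log.info("descriptives written for %d traits", len(desc))

    # align expression columns with QC-passing individuals
    keep_ids = [i for i in counts.individual_ids if i in set(kept["id"])]
    col_idx = [counts.individual_ids.index(i) for i in keep_ids]
    counts_kept = type(counts)(
        counts=counts.counts[:, col_idx],
        feature_meta=counts.feature_meta,
        individual_ids=keep_ids,
    )
    kept = kept.set_index("id").loc[keep_ids].reset_index()

    # ---- stage: expression --------------------------------------------
    filtered = filter_expressed(counts_kept, config.min_count, config.min_frac)
    log.info("expressed filter (count>=%d in >%d%% of individuals): %d -> %d features",
             config.min_count, int(config.min_frac * 100),
             counts_kept.n_features, filtered.n_features)
    factors = tmm_factors(filtered, config.trim_m, config.trim_a)
    tio.write_factors_tsv(filtered.individual_ids, factors, outdir / "tmm_factors.tsv")
    expr = cpm(filtered, factors)
    std = standardize(expr)
    log.info("TMM+CPM+standardize: %d features, %d individuals retained",
             std.n_features, std.n_individuals)
    if config.save_matrices:
        tio.write_expression_tsv(expr, outdir / "cpm.tsv")
        tio.write_expression_tsv(std, outdir / "standardized.tsv")

    # ---- stage: relationship ------------------------------------------
    orm = build_orm(std)
    tio.write_orm_tsv(orm, outdir / "orm.tsv")
    log.info("ORM built: n=%d, m=%d, mean diag=%.6f", orm.n, orm.m_features,
             float(np.mean(np.diag(orm.A))))

    # ---- stages: varcomp + association per trait ----------------------
    X = design_from_phenotypes(kept)
    rng_boot = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    var_rows, assoc, inflation, reports = [], {}, {}, {}
    for trait in config.traits:
        y = kept[trait].to_numpy(dtype=float)
        if np.isnan(y).any():
            log.warning("%s: missing values; trait skipped", trait)
            continue
        fit = fit_reml(y, X, orm)
        row = {"trait": trait, "level": config.level, **fit.as_row()}
        var_rows.append(row)
        if not fit.converged:
            log.warning("%s: REML not converged (%s); association skipped",
                        trait, fit.message)
            continue
        log.info("%s: REML rho2=%.3f (SE %.3f), sigma_o2=%.4g, sigma_e2=%.4g",
                 trait, fit.rho2, fit.se_rho2, fit.sigma_o2, fit.sigma_e2)
        try:
            prelim = moa_scan(y, X, std, orm, null_fit=fit)
            res = moment_test(y, X, std, prelim, bins=config.moment_bins,
                              null_fit=fit)
        except RuntimeError as exc:
            log.warning("%s: association stage failed: %s", trait, exc)
            continue
        assoc[trait] = res
        res.to_csv(outdir / f"assoc_{trait}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        infl = inflation_factor(res["chi2"].to_numpy(), n_boot=config.n_boot,
                                seed=rng_boot)
        inflation[trait] = infl
        rep = significance_report(res, alpha=config.alpha, top_k=config.top_k)
        reports[trait] = rep
        rep.suggestive.to_csv(outdir / f"suggestive_{trait}.tsv", sep="\t",
                              index=False, float_format="%.6g")
        log.info("%s: lambda=%.3f (%.3f-%.3f), threshold=%.3g, significant=%d",
                 trait, infl.lam, infl.ci_low, infl.ci_high, rep.threshold,
                 rep.n_significant)
        if config.make_plots:
            _plots(res, outdir, trait)

    var_report = pd.DataFrame(var_rows)
    _write_var_report(var_report, outdir / "variance_components.tsv")
    if inflation:
        pd.DataFrame(
            [
                {"trait": t, "lambda": v.lam, "ci_low": v.ci_low,
                 "ci_high": v.ci_high, "n_tests": v.n_tests}
                for t, v in inflation.items()
            ]
        ).to_csv(outdir / "inflation.tsv", sep="\t", index=False,
                 float_format="%.4f")
    log.info("run complete in %.1f s", time.time() - t0)
    return {
        "phenotypes": pheno,
        "descriptives": desc,
        "correlations": corr,
        "orm": orm,
        "variance_components": var_report,
        "association": assoc,
        "inflation": inflation,
        "significance": reports,
        "outdir": outdir,
    }


def _write_var_report(var_report: pd.DataFrame, path: Path) -> None:
    """Variance report with explicit 'Not converged' rows."""
    rows = []
    for _, r in var_report.iterrows():
        if not r["converged"]:
            rows.append({"trait": r["trait"], "level": r["level"],
                         "sigma_o2": "Not converged", "sigma_e2": "", "rho2": ""})
        else:
            rows.append({
                "trait": r["trait"], "level": r["level"],
                "sigma_o2": f"{r['sigma_o2']:.4g} ± {r['se_sigma_o2']:.4g}",
                "sigma_e2": f"{r['sigma_e2']:.4g} ± {r['se_sigma_e2']:.4g}",
                "rho2": f"{r['rho2']:.3f} ± {r['se_rho2']:.3f}",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _plots(res: pd.DataFrame, outdir: Path, trait: str) -> None:
    """Minimal Manhattan and QQ plots (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    offset, ticks = 0.0, []
    for chrom, grp in res.groupby("chromosome", sort=True):
        x = grp["start"].to_numpy(float)
        x = offset + (x - x.min()) / max(x.ptp(), 1.0)
        axes[0].scatter(x, -np.log10(grp["p_value"]), s=4,
                        color="C0" if int(chrom) % 2 else "C1")
        ticks.append((offset + 0.5, str(chrom)))
        offset += 1.0
    axes[0].set_xticks([t for t, _ in ticks], [l for _, l in ticks], fontsize=6)
    axes[0].set_xlabel("chromosome")
    axes[0].set_ylabel("-log10 p")
    axes[0].set_title(f"{trait}: Manhattan")
    p = np.sort(res["p_value"].to_numpy())
    exp = -np.log10((np.arange(p.size) + 0.5) / p.size)
    axes[1].scatter(exp, -np.log10(p), s=4)
    lim = max(exp.max(), -np.log10(p.min()))
    axes[1].plot([0, lim], [0, lim], "k--", lw=0.8)
    axes[1].set_xlabel("expected -log10 p")
    axes[1].set_ylabel("observed -log10 p")
    axes[1].set_title(f"{trait}: QQ")
    fig.tight_layout()
    fig.savefig(outdir / f"plots_{trait}.png", dpi=120)
    plt.close(fig)
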