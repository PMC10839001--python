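"""Growth-phenotype curation: MAD outlier QC, average daily gain, and
descriptive reporting.

Body weight (BW, grams) is recorded at 35, 56, 70 and 84 days of age.
Records are quality controlled per time point by the robust rule
median +/- k * MAD (k = 3 by default); an individual that fails at any
time point is excluded entirely.  Average daily gain (ADG, g/day) is then
derived for the three post-weaning periods ending at 84 days:

    adg35 = (bw84 - bw35) / 49
    adg56 = (bw84 - bw56) / 28
    adg70 = (bw84 - bw70) / 14

The descriptive report gives mean, sample SD, min, max and the mean/SD
ratio per trait, plus Pearson correlations between traits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "BW_COLUMNS",
    "ADG_PERIODS",
    "mad_outlier_mask",
    "apply_qc",
    "derive_adg",
    "descriptive_stats",
    "trait_correlations",
]

BW_COLUMNS = ("bw35", "bw56", "bw70", "bw84")

# (adg column, starting bw column, period length in days; all periods end at bw84)
ADG_PERIODS = (
    ("adg35", "bw35", 49),
    ("adg56", "bw56", 28),
    ("adg70", "bw70", 14),
)

#: Gaussian consistency constant: MAD * 1.4826 estimates the SD of a normal
MAD_CONSISTENCY = 1.4826


def mad_outlier_mask(
    values: np.ndarray, k: float = 3.0, c: float = MAD_CONSISTENCY
) -> np.ndarray:
    """True where a value lies within median +/- k * c * MAD.

    ``c`` is the consistency constant applied to the raw median absolute
    deviation (1.4826 makes the scaled MAD estimate a normal SD; set
    ``c=1.0`` for the literal raw-MAD rule).  Missing values are masked
    False.  A degenerate spread (MAD = 0) collapses the interval to the
    median itself; only exact-median values survive and a warning is
    emitted.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values for MAD QC")
    med = np.median(x[finite])
    mad_s = c * np.median(np.abs(x[finite] - med))
    if mad_s == 0:
        warnings.warn(
            "degenerate spread (MAD = 0): only exact-median values retained",
            RuntimeWarning,
        )
        return finite & (x == med)
    return finite & (x >= med - k * mad_s) & (x <= med + k * mad_s)


def apply_qc(
    table: pd.DataFrame, k: float = 3.0, c: float = MAD_CONSISTENCY
) -> pd.DataFrame:
    """Flag individuals failing the MAD rule at any BW time point.

    Returns a copy with a boolean ``qc_pass`` column; exclusion is
    individual-wise across all four time points.
    """
    out = table.copy()
    ok = np.ones(len(out), dtype=bool)
    for col in BW_COLUMNS:
        if col in out.columns:
            vals = out[col].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError(f"{col}: body weights must be strictly positive")
            ok &= mad_outlier_mask(vals, k=k, c=c)
    out["qc_pass"] = ok
    return out


def derive_adg(table: pd.DataFrame) -> pd.DataFrame:
    """Add ADG columns for the three periods ending at 84 days.

    ADG is set only for individuals passing QC with both endpoint weights
    present; negative gains are kept (logged as a warning), missing
    endpoints give missing ADG.
    """
    out = table.copy()
    if "qc_pass" not in out.columns:
        out["qc_pass"] = True
    passed = out["qc_pass"].to_numpy(bool)
    bw84 = out["bw84"].to_numpy(dtype=float)
    for adg_col, start_col, days in ADG_PERIODS:
        start = out[start_col].to_numpy(dtype=float)
        adg = (bw84 - start) / days
        adg[~passed] = np.nan
        if np.any(adg[np.isfinite(adg)] < 0):
            warnings.warn(f"{adg_col}: negative daily gain present", RuntimeWarning)
        out[adg_col] = adg
    return out


def descriptive_stats(table: pd.DataFrame, trait: str) -> dict:
    """Mean, sample SD, min, max and the mean/SD ratio for one trait.

    Values are rounded to 2 decimals for report output.  The mean/SD
    ratio (a signal-to-noise summary sometimes printed in a table column
    labelled CV) is reported missing for a constant trait.
    """
    sub = table[table["qc_pass"]] if "qc_pass" in table.columns else table
    x = sub[trait].dropna().to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError(f"{trait}: need at least 2 observations")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    ratio = mean / sd if sd > 0 else np.nan
    return {
        "trait": trait,
        "n": int(x.size),
        "mean": round(mean, 2),
        "sd": round(sd, 2),
        "min": round(float(np.min(x)), 2),
        "max": round(float(np.max(x)), 2),
        "mean_sd_ratio": round(ratio, 2) if np.isfinite(ratio) else np.nan,
    }


def trait_correlations(
    table: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations over complete cases per pair."""
    if traits is None:
        traits = [c for c in ("bw84", "adg35", "adg56", "adg70") if c in table.columns]
    sub = table[table["qc_pass"]][traits] if "qc_pass" in table.columns else table[traits]
    corr = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j in range(i + 1, len(traits)):
            b = traits[j]
            pair = sub[[a, b]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete cases for {a} vs {b}")
            va, vb = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if va.std() == 0 or vb.std() == 0:
                warnings.warn(
                    f"zero-variance trait in pair ({a}, {b}); correlation missing",
                    RuntimeWarning,
                )
                r = np.nan
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            corr.loc[a, b] = corr.loc[b, a] = r
    return corr
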