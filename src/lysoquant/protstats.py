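"""Differential-abundance statistics for organelle proteomics.

Fixed pipeline order: validity filter -> quantile normalization -> missing-
not-at-random (downshift) imputation -> empirical-Bayes moderated t ->
Benjamini-Hochberg adjustment.  All statistics operate on the log2 scale;
in SILAC mode the values are log2 heavy/light ratios centered on 0, in LFQ
mode log2 intensities.

The moderated t shrinks each protein's residual variance s2_g (d_g degrees
of freedom) toward a prior s0_2 with d0 degrees of freedom estimated from
the whole ensemble by moment-matching the scaled-F model on log s2_g:

    s2_post = (d0 * s0_2 + d_g * s2_g) / (d0 + d_g)
    t_mod   = log2FC / (s_post * sqrt(1/n_A + 1/n_B)),   df = d0 + d_g
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_valid(
    matrix: pd.DataFrame, design: pd.DataFrame, min_valid_fraction: float = 0.70
) -> pd.DataFrame:
    """Keep proteins quantified in >= 70% of samples of at least one condition.

    The fraction is computed against that condition's own sample count and
    compared with >= (so 4/5 = 0.8 passes, 3/5 = 0.6 fails at the default).
    """
    keep = pd.Series(False, index=matrix.index)
    for cond, grp in design.groupby("condition"):
        cols = grp["sample"].tolist()
        frac = matrix[cols].notna().mean(axis=1)
        keep |= frac >= min_valid_fraction
    return matrix.loc[keep]


def quantile_normalize(matrix: pd.DataFrame, groups: dict | None = None) -> pd.DataFrame:
    """Quantile-normalize observed values column-wise; missing entries stay missing.

    Every complete column acquires the identical sorted value vector (the
    across-column mean quantile function); columns with missing entries are
    mapped through their observed fractional ranks, ties averaged.  When
    ``groups`` maps sample to group label, normalization runs independently
    within each group — forcing identical marginals across biologically
    different fraction types erases genuine composition differences, so the
    fraction-enrichment pipeline normalizes within fraction type.
    """
    if matrix.shape[1] < 2 and groups is None:
        raise ValueError("quantile normalization needs >= 2 samples")
    out = matrix.astype(float).copy()
    if groups is None:
        col_groups = {None: list(matrix.columns)}
    else:
        col_groups = {}
        for col in matrix.columns:
            col_groups.setdefault(groups[col], []).append(col)
    n_rows = len(matrix)
    grid = np.linspace(0.0, 1.0, n_rows) if n_rows > 1 else np.array([0.5])
    for cols in col_groups.values():
        quantile_funcs = []
        for col in cols:
            obs = np.sort(matrix[col].dropna().to_numpy(dtype=float))
            if obs.size == 0:
                raise ValueError(f"sample {col!r} has no observed values")
            pos = np.linspace(0.0, 1.0, obs.size) if obs.size > 1 else np.array([0.5])
            quantile_funcs.append(np.interp(grid, pos, obs))
        reference = np.mean(quantile_funcs, axis=0)
        for col in cols:
            vals = matrix[col].to_numpy(dtype=float)
            mask = ~np.isnan(vals)
            obs = vals[mask]
            ranks = stats.rankdata(obs, method="average")
            frac = (ranks - 1.0) / (obs.size - 1.0) if obs.size > 1 else np.array([0.5])
            new = vals.copy()
            new[mask] = np.interp(frac, grid, reference)
            out[col] = new
    return out


# ---------------------------------------------------------------------------
# imputation


@dataclass
class ImputationParams:
    """Downshifted/narrowed imputation of censored low-abundance values.

    LFQ mode draws Normal(mu_s - downshift*sigma_s, (width*sigma_s)^2) per
    sample s; SILAC mode centers on 0 (log-ratio scale) with the same
    narrowed width.  Defaults follow the Perseus convention (1.8 / 0.3).
    """

    downshift: float = 1.8
    width: float = 0.3
    mode: str = "lfq"  # "lfq" | "silac"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")
        if self.mode not in ("lfq", "silac"):
            raise ValueError(f"unknown imputation mode {self.mode!r}")


def impute(matrix: pd.DataFrame, params: ImputationParams) -> pd.DataFrame:
    """Replace missing entries by per-sample downshifted Normal draws.

    Observed entries are untouched; a fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    out = matrix.astype(float).copy()
    for col in out.columns:
        vals = out[col].to_numpy(dtype=float)
        mask = np.isnan(vals)
        if not mask.any():
            continue
        obs = vals[~mask]
        if obs.size < 2:
            raise ValueError(f"sample {col!r} has < 2 observed values; sigma undefined")
        mu, sigma = obs.mean(), obs.std(ddof=1)
        center = 0.0 if params.mode == "silac" else mu - params.downshift * sigma
        vals[mask] = rng.normal(center, params.width * sigma, mask.sum())
        out[col] = vals
    return out


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0_2) of the scaled-F model from sample variances.

    Works on e_g = log s2_g - digamma(d_g/2) + log(d_g/2); the mean of e
    locates s0_2 and the excess variance of e over trigamma(d_g/2) locates
    d0.  No excess variance gives d0 = inf (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    finite = s2 > 0
    if not finite.any():
        raise ValueError("all residual variances are zero; prior is unidentifiable")
    z = np.log(s2[finite])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    excess = (e - e_mean) @ (e - e_mean) / (n - 1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group empirical-Bayes moderated t per protein.

    ``contrast = (A, B)`` tests mean(A) - mean(B) on the (complete, post-
    imputation) matrix.  ``d0_override`` forces the prior degrees of freedom
    (0 reduces to the ordinary pooled t; inf shrinks every variance to s0_2).
    Proteins with zero residual variance everywhere make the prior
    unidentifiable; the documented fallback is the ordinary t (d0 = 0).
    """
    cond_a, cond_b = contrast
    cols_a = design.loc[design["condition"] == cond_a, "sample"].tolist()
    cols_b = design.loc[design["condition"] == cond_b, "sample"].tolist()
    n_a, n_b = len(cols_a), len(cols_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each contrast condition needs >= 2 samples")
    if matrix[cols_a + cols_b].isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    a = matrix[cols_a].to_numpy(dtype=float)
    b = matrix[cols_b].to_numpy(dtype=float)
    fc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_res = n_a + n_b - 2
    s2 = ss / df_res

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(np.exp(np.mean(np.log(s2[s2 > 0])))) if np.any(s2 > 0) else 0.0
        if d0 == 0:
            s0_2 = 0.0
    else:
        try:
            d0, s0_2 = estimate_prior_variance(s2, df_res)
        except ValueError:
            d0, s0_2 = 0.0, 0.0  # fallback: ordinary t

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2fc": fc,
            "s2": s2,
            "df_residual": df_res,
            "s2_prior": s0_2,
            "df_prior": d0,
            "s2_post": s2_post,
            "t_mod": t,
            "p_value": p,
            "adj_p_value": bh_adjust(p),
        },
        index=matrix.index,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def one_sample_t(values, popmean: float = 1.0) -> tuple[float, float]:
    """Textbook one-sample t against a hypothetical mean (two-sided p)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 values")
    t = (x.mean() - popmean) / (x.std(ddof=1) / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# compartment enrichment and densitometry


def class_enrichment(
    matrix: pd.DataFrame,
    classes: pd.Series,
    design: pd.DataFrame,
    contrast: tuple[str, str] = ("lyso", "PNS"),
    background_class: str = "other",
    lysosomal_cutoff_log2fc: float = 2.0,
) -> dict:
    """Per-class fold enrichment in the organelle fraction over the background.

    Each protein's enrichment e_g is its mean log2 difference between the
    fraction and lysate samples; a class's fold is
    2**(mean_class e_g) / 2**(mean_background e_g).  The operational
    "lysosomal" call applies the log2FC > 2 cut-off to e_g.
    """
    cond_a, cond_b = contrast
    cols_a = design.loc[design["condition"] == cond_a, "sample"].tolist()
    cols_b = design.loc[design["condition"] == cond_b, "sample"].tolist()
    e = matrix[cols_a].mean(axis=1) - matrix[cols_b].mean(axis=1)
    cls = classes.reindex(e.index)
    bg = e[cls == background_class]
    if bg.empty:
        raise ValueError(f"no proteins of background class {background_class!r}")
    bg_mean = bg.mean()
    folds = {
        str(c): float(2.0 ** (e[cls == c].mean() - bg_mean))
        for c in cls.dropna().unique()
    }
    return {
        "per_protein_log2_enrichment": e,
        "class_fold": folds,
        "lysosomal_call": e > lysosomal_cutoff_log2fc,
    }


def relative_band_abundance(
    target: dict[str, float],
    references: dict[str, list[float]],
    control: str,
) -> pd.Series:
    """Densitometry ratio of a target band over ubiquitous reference bands.

    Per condition: (target / mean of references), then normalized to the
    control condition so the control ratio is exactly 1.
    """
    ratios = {}
    for cond, t in target.items():
        refs = np.asarray(references[cond], dtype=float)
        if np.any(refs <= 0):
            raise ValueError(f"non-positive reference intensity in condition {cond!r}")
        ratios[cond] = t / refs.mean()
    if control not in ratios:
        raise KeyError(f"control condition {control!r} missing")
    base = ratios[control]
    if base == 0:
        raise ValueError("control ratio is zero")
    return pd.Series({c: r / base for c, r in ratios.items()}, name="relative_abundance")
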