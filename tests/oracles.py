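"""Independent brute-force oracles used by the test suite.

Each oracle is written directly from the defining formula or procedure and
stays independent of the package code paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def medpolish_residuals_oracle(grid: np.ndarray, n_sweeps: int = 800) -> np.ndarray:
    """Residuals of a two-way median polish by plain alternating sweeps.

    Repeatedly subtracts row medians then column medians (NaN-aware) for a
    fixed number of sweeps (stopping early only once a sweep moves nothing
    at all) and returns what is left.
    """
    import warnings

    resid = np.array(grid, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for _ in range(n_sweeps):
            rm = np.nanmedian(resid, axis=1)
            rm[~np.isfinite(rm)] = 0.0
            resid -= rm[:, None]
            cm = np.nanmedian(resid, axis=0)
            cm[~np.isfinite(cm)] = 0.0
            resid -= cm[None, :]
            if np.abs(rm).sum() + np.abs(cm).sum() == 0.0:
                break
    return resid


def robust_z_oracle(value: float, reference: list[float]) -> float:
    """Median/MAD z-score computed stepwise from the definition."""
    ref = sorted(reference)
    med = float(np.median(ref))
    mad = float(np.median([abs(x - med) for x in ref]))
    return (value - med) / (1.4826 * mad)


def ttest_oracle(a, b) -> tuple[float, float, float]:
    """Equal-variance two-sample t-test from the textbook formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def anova_F_oracle(groups) -> tuple[float, float]:
    """One-way ANOVA F from explicit between/within sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), p


def tukey_p_oracle(groups, i: int, j: int) -> float:
    """Tukey HSD adjusted p for one pair via the studentized range."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    df_w = sum(g.size for g in groups) - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    ni, nj = groups[i].size, groups[j].size
    se = np.sqrt(mse / 2.0 * (1.0 / ni + 1.0 / nj))
    q = abs(groups[i].mean() - groups[j].mean()) / se
    return float(sps.studentized_range.sf(q, k, df_w))


def enumerate_background_boxes(
    image: np.ndarray, mask: np.ndarray, box_size: int = 8
) -> np.ndarray:
    """Per-box maxima of every admissible box fully inside the mask."""
    h, w = mask.shape
    out = []
    for r in range(h - box_size + 1):
        for c in range(w - box_size + 1):
            if mask[r : r + box_size, c : c + box_size].all():
                out.append(image[r : r + box_size, c : c + box_size].max())
    return np.asarray(out, dtype=float)
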