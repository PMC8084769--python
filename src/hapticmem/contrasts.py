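"""Planned contrasts and repeated-measures statistics on JNDs and PSEs.

Paired t tests with Cohen's d_z, linear contrasts over stroke number,
Cousineau-Morey within-participant standard errors, Bonferroni correction,
and a repeated-measures ANOVA (delegated to pingouin) with Huynh-Feldt
sphericity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastResult",
    "paired_t",
    "linear_contrast",
    "stroke_contrast",
    "morey_sem",
    "bonferroni",
    "rm_anova",
]


@dataclass
class ContrastResult:
    statistic: float
    df: int
    p: float
    tail: str
    effect_size: float  # Cohen's d_z


_TAILS = {"two", "greater", "less"}


def _one_sample_t(d: np.ndarray, tail: str) -> ContrastResult:
    if tail == "one":
        tail = "greater"
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {sorted(_TAILS)} (or 'one')")
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 paired observations")
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0:
        if m == 0:
            return ContrastResult(0.0, n - 1, 1.0 if tail == "two" else 0.5, tail, 0.0)
        raise ValueError("zero-variance difference with nonzero mean: t undefined")
    t = m / (sd / np.sqrt(n))
    df = n - 1
    if tail == "two":
        p = 2 * stats.t.sf(abs(t), df)
    elif tail == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return ContrastResult(float(t), df, float(p), tail, float(m / sd))


def paired_t(x, y, tail: str = "two") -> ContrastResult:
    """Paired t test on per-participant values; d_z = mean(x-y)/sd(x-y).

    ``tail='greater'`` tests mean(x - y) > 0 (``'one'`` is an alias);
    a zero-variance difference with nonzero mean raises rather than
    returning an infinite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length (paired by participant)")
    return _one_sample_t(x - y, tail)


def linear_contrast(values, weights=(-3, -1, 1, 3), tail: str = "two") -> ContrastResult:
    """One-sample t on per-participant linear-contrast scores.

    ``values`` is a participants x levels matrix (DataFrame or array) of
    condition means; ``weights`` are centered contrast weights over the
    levels (default the orthogonal linear weights for four equally spaced
    levels).  Note that for stroke numbers 1, 3, 5, 7 the centered raw
    counts are proportional to (-3, -1, 1, 3), so rank- and value-spaced
    weights coincide.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("values must be a participants x levels matrix")
    if np.isnan(m).any():
        raise ValueError("incomplete matrix: NaNs present")
    w = np.asarray(weights, dtype=float)
    if w.size != m.shape[1]:
        raise ValueError("weights length must match the number of levels")
    if abs(w.sum()) > 1e-9:
        raise ValueError("contrast weights must sum to zero")
    scores = m @ w
    return _one_sample_t(scores, tail)


def stroke_contrast(
    jnd_table: pd.DataFrame,
    value_col: str = "jnd_mm",
    interaction: bool = False,
    tail: str = "two",
) -> ContrastResult:
    """Linear contrast of stroke number from a tidy per-condition table.

    Main effect: per-participant condition means averaged over masking at
    each stroke number.  ``interaction=True`` instead contrasts the
    masked-minus-unmasked difference across stroke numbers (difference of
    slopes).
    """
    df = jnd_table
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    wide = df.pivot_table(
        index="participant", columns=["masked", "n1"], values=value_col
    )
    levels = sorted({n1 for (_, n1) in wide.columns})
    if interaction:
        m = np.column_stack(
            [wide[(True, n1)] - wide[(False, n1)] for n1 in levels]
        )
    else:
        m = np.column_stack(
            [0.5 * (wide[(True, n1)] + wide[(False, n1)]) for n1 in levels]
        )
    return linear_contrast(m, tail=tail)


def morey_sem(matrix) -> pd.Series:
    """Within-participant standard errors after Cousineau-Morey.

    Each participant's mean is removed (and the grand mean restored) before
    computing per-condition SEMs, which are then inflated by
    ``sqrt(C/(C-1))`` for the C conditions.
    """
    m = pd.DataFrame(matrix)
    if m.isna().any().any():
        raise ValueError("incomplete matrix: NaNs present")
    n, c = m.shape
    if n < 2 or c < 2:
        raise ValueError("need >= 2 participants and >= 2 conditions")
    normalized = m.sub(m.mean(axis=1), axis=0) + m.to_numpy().mean()
    sem = normalized.std(ddof=1) / np.sqrt(n)
    return sem * np.sqrt(c / (c - 1))


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p value, capped at 1."""
    return min(1.0, p * n_tests)


def _hf_from_gg(eps_gg: float, n: int, k: int) -> float:
    # Huynh-Feldt epsilon from the Greenhouse-Geisser estimate
    num = n * (k - 1) * eps_gg - 2
    den = (k - 1) * ((n - 1) - (k - 1) * eps_gg)
    if den <= 0:
        return 1.0
    return min(1.0, num / den)


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """Repeated-measures ANOVA (one or two within factors) via pingouin.

    Returns a tidy table (effect, F, df1, df2, p, p_corr, partial_eta2,
    eps_hf).  ``p_corr`` applies the Huynh-Feldt sphericity correction when
    the effect has more than one numerator df and the estimated epsilon is
    below 1; otherwise it equals the uncorrected p.  The design must be
    complete and balanced.
    """
    import pingouin as pg

    if isinstance(within, str):
        within = [within]
    counts = data.groupby([subject, *within], observed=True)[dv].count()
    n_cells = data[subject].nunique() * int(
        np.prod([data[f].nunique() for f in within])
    )
    if counts.nunique() != 1 or len(counts) != n_cells:
        raise ValueError("unbalanced design: unequal or missing cell counts")
    n = data[subject].nunique()
    aov = pg.rm_anova(
        data=data, dv=dv, within=list(within), subject=subject,
        detailed=True, effsize="np2",
    )
    rows = []
    for _, r in aov.iterrows():
        src = r["Source"]
        if src in ("Error", "Within"):
            continue
        df1 = float(r["ddof1"] if "ddof1" in r else r["DF"])
        df2 = float(r["ddof2"] if "ddof2" in r else df1 * (n - 1))
        if "SS" in r and float(r["SS"]) == 0.0:
            # no effect variance at all: F is 0 by convention
            rows.append(
                {"effect": src, "F": 0.0, "df1": df1, "df2": df2, "p": 1.0,
                 "p_corr": 1.0, "partial_eta2": 0.0, "eps_hf": 1.0}
            )
            continue
        if not np.isfinite(r.get("F", np.nan)):
            continue
        F = float(r["F"])
        p = float(r["p_unc"])
        k = int(round(df1)) + 1
        eps_hf = 1.0
        p_corr = p
        if df1 >= 2:
            eps_raw = r.get("eps", np.nan)
            eps_gg = float(eps_raw) if np.isfinite(eps_raw) else 1.0
            eps_hf = _hf_from_gg(eps_gg, n, k)
            if eps_hf < 1.0:
                p_corr = float(stats.f.sf(F, df1 * eps_hf, df2 * eps_hf))
        rows.append(
            {
                "effect": src,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "p_corr": p_corr,
                "partial_eta2": float(r["np2"]),
                "eps_hf": eps_hf,
            }
        )
    return pd.DataFrame(rows)
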