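"""Repeated-measures factorial statistics and map-correlation summaries.

Every species receives all 12 treatments (3 predictor sets × 4 algorithms),
so treatment effects on a metric are tested with a two-factor
within-subject (repeated-measures) ANOVA: species are subjects, Predictor
and Algorithm are within-subject factors.  Each effect has its own error
stratum (the subject × effect interaction).  Sphericity of each effect's
orthonormal-contrast covariance is checked with Mauchly's W (chi-square
approximation with the standard small-sample factor); when rejected at
α = 0.05 the degrees of freedom are shrunk by the Greenhouse–Geisser
epsilon ``ε̂ = (Σλ)² / (q Σλ²)``.

For a balanced complete design Type I and Type III sums of squares
coincide, so the plain decomposition below matches the Type III convention
reported for such designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["rm_anova", "RMAnovaResult", "EffectResult",
           "summarize_pairwise_tau", "arcsine_transform"]


@dataclass
class EffectResult:
    name: str
    ss: float
    df: float
    ms: float
    ss_error: float
    df_error: float
    ms_error: float
    F: float
    p_uncorrected: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    df_gg: float
    df_error_gg: float
    p_gg: float
    sphericity_rejected: bool

    @property
    def p_reported(self) -> float:
        """GG-corrected p when Mauchly rejects sphericity, else uncorrected."""
        return self.p_gg if self.sphericity_rejected else self.p_uncorrected


@dataclass
class RMAnovaResult:
    effects: dict[str, EffectResult]
    ss_subject: float
    ss_total: float
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "Effect": e.name,
                    "SumSq": e.ss,
                    "Df": e.df_gg if e.sphericity_rejected else e.df,
                    "MeanSq": e.ms,
                    "F": e.F,
                    "p": e.p_reported,
                    "MauchlyW": e.mauchly_w,
                    "MauchlyP": e.mauchly_p,
                    "GGepsilon": e.gg_epsilon,
                }
            )
        return pd.DataFrame(rows)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    C = np.zeros((k - 1, k))
    for r in range(k - 1):
        C[r, : r + 1] = 1.0
        C[r, r + 1] = -(r + 1.0)
        C[r] /= np.linalg.norm(C[r])
    return C


def _mauchly_gg(D: np.ndarray) -> tuple[float, float, float]:
    """Mauchly W, its chi-square p, and GG epsilon from contrast scores.

    ``D`` is subjects x q (orthonormal contrast scores); the test works on
    the sample covariance of these scores.
    """
    n, q = D.shape
    if q == 1:
        return 1.0, 1.0, 1.0
    S = np.cov(D, rowvar=False, ddof=1)
    eig = np.clip(np.linalg.eigvalsh(S), 0.0, None)
    tr = eig.sum()
    eps = (tr**2) / (q * (eig**2).sum()) if tr > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    pos = eig[eig > 1e-12]
    if len(pos) < q or tr <= 0:
        return 0.0, 0.0, eps  # singular covariance: maximal violation
    logw = float(np.sum(np.log(pos)) - q * np.log(tr / q))
    w = float(np.exp(logw))
    dfw = n - 1
    d = 1.0 - (2 * q**2 + q + 2) / (6.0 * q * dfw)
    chi2 = -dfw * d * logw
    df_chi = q * (q + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df_chi))
    return w, p, eps


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str = "species",
    within: tuple[str, str] = ("predictor", "algorithm"),
    alpha: float = 0.05,
) -> RMAnovaResult:
    """Two-factor within-subject ANOVA with Mauchly test and GG correction.

    ``table`` must be a complete balanced long table: every subject crossed
    with every (within[0], within[1]) combination exactly once.
    """
    fa, fb = within
    piv = table.pivot_table(index=subject, columns=[fa, fb], values=dv)
    if piv.isna().any().any():
        raise ValueError("unbalanced design: missing subject x treatment cells")
    a_levels = sorted({c[0] for c in piv.columns})
    b_levels = sorted({c[1] for c in piv.columns})
    a, b = len(a_levels), len(b_levels)
    n = len(piv)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    # cube: subjects x a x b
    Y = np.empty((n, a, b))
    for i_a, la in enumerate(a_levels):
        for i_b, lb in enumerate(b_levels):
            Y[:, i_a, i_b] = piv[(la, lb)].to_numpy()

    grand = Y.mean()
    subj_mean = Y.mean(axis=(1, 2))
    a_mean = Y.mean(axis=(0, 2))
    b_mean = Y.mean(axis=(0, 1))
    sa_mean = Y.mean(axis=2)  # n x a
    sb_mean = Y.mean(axis=1)  # n x b
    ab_mean = Y.mean(axis=0)  # a x b

    ss_total = float(((Y - grand) ** 2).sum())
    ss_subject = float(a * b * ((subj_mean - grand) ** 2).sum())
    ss_a = float(n * b * ((a_mean - grand) ** 2).sum())
    ss_b = float(n * a * ((b_mean - grand) ** 2).sum())
    ss_ab = float(
        n
        * (
            (ab_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2
        ).sum()
    )
    ss_sa = float(
        b * ((sa_mean - subj_mean[:, None] - a_mean[None, :] + grand) ** 2).sum()
    )
    ss_sb = float(
        a * ((sb_mean - subj_mean[:, None] - b_mean[None, :] + grand) ** 2).sum()
    )
    ss_sab = ss_total - ss_subject - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    CA = _orthonormal_contrasts(a)
    CB = _orthonormal_contrasts(b)
    contrast_scores = {
        fa.capitalize(): np.einsum("qa,na->nq", CA, sa_mean) * np.sqrt(b),
        fb.capitalize(): np.einsum("qb,nb->nq", CB, sb_mean) * np.sqrt(a),
        f"{fa.capitalize()}x{fb.capitalize()}": np.einsum(
            "pa,qb,nab->npq", CA, CB, Y
        ).reshape(n, (a - 1) * (b - 1)),
    }
    specs = [
        (fa.capitalize(), ss_a, a - 1, ss_sa, (n - 1) * (a - 1)),
        (fb.capitalize(), ss_b, b - 1, ss_sb, (n - 1) * (b - 1)),
        (
            f"{fa.capitalize()}x{fb.capitalize()}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_sab,
            (n - 1) * (a - 1) * (b - 1),
        ),
    ]
    effects: dict[str, EffectResult] = {}
    for name, ss, df, ss_err, df_err in specs:
        ms = ss / df
        ms_err = ss_err / df_err
        F = ms / ms_err if ms_err > 0 else np.inf
        p_unc = float(sps.f.sf(F, df, df_err))
        w, pw, eps = _mauchly_gg(contrast_scores[name])
        df_gg, df_err_gg = eps * df, eps * df_err
        p_gg = float(sps.f.sf(F, df_gg, df_err_gg))
        effects[name] = EffectResult(
            name=name, ss=ss, df=df, ms=ms,
            ss_error=ss_err, df_error=df_err, ms_error=ms_err,
            F=float(F), p_uncorrected=p_unc,
            mauchly_w=w, mauchly_p=pw, gg_epsilon=eps,
            df_gg=df_gg, df_error_gg=df_err_gg, p_gg=p_gg,
            sphericity_rejected=pw < alpha,
        )
    return RMAnovaResult(effects, ss_subject, ss_total, n)


def arcsine_transform(x, sqrt_variant: bool = False) -> np.ndarray:
    """Variance-stabilizing arcsine transform of skill values in [-1, 1].

    Default is ``arcsin(x)`` (domain-valid for negative skill); the
    ``arcsin(sqrt(x))`` proportion variant clips negatives to 0.
    """
    x = np.asarray(x, float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("arcsine transform needs values in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    if sqrt_variant:
        return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))
    return np.arcsin(x)


def summarize_pairwise_tau(
    tau_records: pd.DataFrame,
    group: tuple[str, ...] = ("comparison", "pair"),
    value: str = "tau",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Mean and normal-approximation CI of tau per group cell across species."""
    z = sps.norm.ppf(0.5 + conf / 2.0)
    rows = []
    for key, sub in tau_records.groupby(list(group)):
        vals = sub[value].to_numpy(float)
        if len(vals) < 2:
            warnings.warn(f"tau summary cell {key} has fewer than 2 species; skipped")
            continue
        m = vals.mean()
        half = z * vals.std(ddof=1) / np.sqrt(len(vals))
        row = dict(zip(group, key if isinstance(key, tuple) else (key,)))
        row.update({"mean": m, "ci_low": m - half, "ci_high": m + half,
                    "n": len(vals)})
        rows.append(row)
    return pd.DataFrame(rows)
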