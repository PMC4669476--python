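"""Repeated-measures statistics for per-subject network metrics.

A condition x frequency-component within-subject ANOVA is run per metric
(CC, GE or BC) and network kind.  Sphericity is checked per effect with
Mauchly's test; when it indicates a violation (p < 0.05) the Huynh-Feldt
epsilon corrects the degrees of freedom.  Post-hoc comparisons are paired
two-sided t-tests across subjects (uncorrected by default, matching common
reporting practice; Holm/Bonferroni available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncompleteDesignError, InvalidParameterError


@dataclass
class EffectResult:
    """One ANOVA effect: F, dfs, sphericity diagnostics, corrected p."""

    name: str
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    mauchly_w: float
    mauchly_p: float
    eps_gg: float
    eps_hf: float
    df1_corrected: float
    df2_corrected: float
    p_corrected: float
    correction_applied: bool


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects.values()])


def _cell_array(table: pd.DataFrame, dv: str, subject: str,
                factors: tuple[str, str]) -> tuple[np.ndarray, list, list, list]:
    fa, fb = factors
    subjects = sorted(table[subject].unique())
    a_levels = list(dict.fromkeys(table[fa]))
    b_levels = list(dict.fromkeys(table[fb]))
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    Y = np.full((n, a, b), np.nan)
    for (s, la, lb), grp in table.groupby([subject, fa, fb], sort=False):
        if len(grp) != 1:
            raise IncompleteDesignError(
                f"cell (subject={s}, {la}, {lb}) has {len(grp)} rows; expected 1"
            )
        Y[subjects.index(s), a_levels.index(la), b_levels.index(lb)] = grp[dv].iloc[0]
    if np.any(np.isnan(Y)):
        missing = np.argwhere(np.isnan(Y))
        s, i, j = missing[0]
        raise IncompleteDesignError(
            f"missing cell: subject={subjects[s]}, {a_levels[i]}, {b_levels[j]} "
            f"({len(missing)} missing in total)"
        )
    return Y, subjects, a_levels, b_levels


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the constant vector."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def _sphericity(U: np.ndarray) -> tuple[float, float, float, float]:
    """Mauchly W and p, GG and HF epsilon from contrast scores U (n x d)."""
    n, d = U.shape
    if d < 2:
        return 1.0, 1.0, 1.0, 1.0
    S = np.cov(U, rowvar=False, ddof=1)
    tr = np.trace(S)
    if tr <= 0 or np.sum(S * S) == 0:  # no between-level variance at all
        return 1.0, 1.0, 1.0, 1.0
    eps_gg = tr ** 2 / (d * np.sum(S * S))
    eps_hf = min(1.0, (n * d * eps_gg - 2.0) / (d * (n - 1.0 - d * eps_gg)))
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return 0.0, 0.0, eps_gg, eps_hf  # singular: maximal violation
    log_w = logdet - d * np.log(tr / d)
    c = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1.0))
    chi2 = -(n - 1.0) * c * log_w
    df = d * (d + 1) / 2.0 - 1.0
    p = float(stats.chi2.sf(chi2, df))
    return float(np.exp(log_w)), p, float(eps_gg), float(eps_hf)


def _f_p(ss_eff: float, ss_err: float, df1: float, df2: float) -> tuple[float, float]:
    if ss_err <= 0:
        return 0.0, 1.0
    F = (ss_eff / df1) / (ss_err / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


def rm_anova(table: pd.DataFrame, dv: str = "value", subject: str = "subject",
             factors: tuple[str, str] = ("condition", "component"),
             mauchly_alpha: float = 0.05) -> AnovaResult:
    """Two-way within-subject ANOVA with sphericity handling.

    ``table`` must be a complete, balanced long-format table with one row
    per (subject, factor-A level, factor-B level).  For every effect the
    uncorrected F/p, Mauchly's test, Greenhouse-Geisser and Huynh-Feldt
    epsilons and the Huynh-Feldt-corrected p are reported; the correction
    counts as "applied" when Mauchly p < ``mauchly_alpha`` (two-level
    factors trivially satisfy sphericity, epsilon = 1).
    """
    Y, subjects, a_levels, b_levels = _cell_array(table, dv, subject, factors)
    n, a, b = Y.shape
    if n < 3:
        raise IncompleteDesignError(f"need >= 3 subjects, got {n}")

    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    resid = (Y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - gm)
    ss_abs = np.sum(resid ** 2)

    C_a = _orthonormal_contrasts(a)
    C_b = _orthonormal_contrasts(b)
    scores = {
        factors[0]: m_sa @ C_a.T,
        factors[1]: m_sb @ C_b.T,
        f"{factors[0]}*{factors[1]}": Y.reshape(n, a * b) @ np.kron(C_a, C_b).T,
    }
    plan = {
        factors[0]: (ss_a, ss_as, a - 1.0),
        factors[1]: (ss_b, ss_bs, b - 1.0),
        f"{factors[0]}*{factors[1]}": (ss_ab, ss_abs, (a - 1.0) * (b - 1.0)),
    }
    effects = {}
    for name, (ss_eff, ss_err, df1) in plan.items():
        df2 = df1 * (n - 1.0)
        F, p_unc = _f_p(ss_eff, ss_err, df1, df2)
        w, p_w, eps_gg, eps_hf = _sphericity(scores[name])
        df1c, df2c = eps_hf * df1, eps_hf * df2
        p_corr = 1.0 if F == 0 else float(stats.f.sf(F, df1c, df2c))
        effects[name] = EffectResult(
            name=name, F=F, df1=df1, df2=df2, p_uncorrected=p_unc,
            mauchly_w=w, mauchly_p=p_w, eps_gg=eps_gg, eps_hf=eps_hf,
            df1_corrected=df1c, df2_corrected=df2c, p_corrected=p_corr,
            correction_applied=bool(p_w < mauchly_alpha),
        )
    return AnovaResult(effects=effects)


def paired_posthoc(table: pd.DataFrame, effect: str,
                   comparisons: list[tuple[str, str]] | None = None,
                   dv: str = "value", subject: str = "subject",
                   correction: str | None = None) -> pd.DataFrame:
    """Paired two-sided t-tests between levels of one factor.

    Values are averaged over the other factor(s) per subject first.
    ``correction`` may be ``None`` (default, matching uncorrected
    reporting), ``"bonferroni"`` or ``"holm"``.
    """
    if effect not in table.columns:
        raise InvalidParameterError(f"unknown effect column {effect!r}")
    wide = table.groupby([subject, effect], sort=False)[dv].mean().unstack(effect)
    levels = list(wide.columns)
    if comparisons is None:
        comparisons = [(levels[i], levels[j]) for i in range(len(levels))
                       for j in range(i + 1, len(levels))]
    rows = []
    for la, lb in comparisons:
        for lev in (la, lb):
            if lev not in levels:
                raise InvalidParameterError(f"unknown level {lev!r} of {effect!r}")
        d = wide[la].to_numpy() - wide[lb].to_numpy()
        n = len(d)
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(wide[la].to_numpy(), wide[lb].to_numpy())
        rows.append({"level_a": la, "level_b": lb, "t": float(t),
                     "df": n - 1, "p": float(p),
                     "mean_diff": float(np.mean(d))})
    out = pd.DataFrame(rows)
    if correction is not None:
        p = out["p"].to_numpy()
        m = len(p)
        if correction == "bonferroni":
            out["p_corrected"] = np.minimum(p * m, 1.0)
        elif correction == "holm":
            order = np.argsort(p)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p[idx])
                adj[idx] = min(running, 1.0)
            out["p_corrected"] = adj
        else:
            raise InvalidParameterError(f"unknown correction {correction!r}")
    return out
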