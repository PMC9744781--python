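"""Repeated-measures inference: within-subject ANOVA with Greenhouse-Geisser
correction and partial eta squared, Tukey HSD post hocs, and the fixed
battery of category contrasts run on the marker feature table.

The ANOVA is a balanced fully-crossed within-subject decomposition with
subject as the random blocking factor: each within effect is tested against
its own effect-by-subject interaction. Sphericity is handled by the
Greenhouse-Geisser epsilon (reported even when it equals 1, as for any
two-level factor).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .features import VISUAL_CATEGORIES, MarkerDefinition, marker_registry
from .montage import homolog

__all__ = [
    "EffectResult", "AnovaResult", "PosthocResult",
    "rm_anova", "gg_epsilon", "tukey_hsd", "run_paper_contrasts",
]


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    epsilon: float
    p_adjusted: float
    partial_eta_sq: float

    def as_dict(self) -> dict:
        return {
            "F": self.F, "df_num": self.df_num, "df_den": self.df_den,
            "p": self.p, "epsilon": self.epsilon,
            "p_adjusted": self.p_adjusted,
            "partial_eta_sq": self.partial_eta_sq,
        }


@dataclass
class AnovaResult:
    """Per-effect repeated-measures ANOVA summary."""

    effects: dict[str, EffectResult]
    n_subjects: int
    factors: dict[str, list] = field(default_factory=dict)

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def as_dict(self) -> dict:
        return {k: v.as_dict() for k, v in self.effects.items()}


@dataclass
class PosthocResult:
    """All-pairs Tukey HSD table: level_a, level_b, mean difference,
    studentized-range adjusted p."""

    pairs: pd.DataFrame

    def p_value(self, a, b) -> float:
        m = self.pairs[
            ((self.pairs.level_a == a) & (self.pairs.level_b == b))
            | ((self.pairs.level_a == b) & (self.pairs.level_b == a))
        ]
        if m.empty:
            raise KeyError(f"no pair ({a}, {b})")
        return float(m.p_adjusted.iloc[0])


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def gg_epsilon(condition_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a k x k condition covariance matrix.

    Computed from the eigenvalues of the double-centered covariance and
    clipped to its theoretical range [1/(k-1), 1]; equals 1 under compound
    symmetry (and always for k = 2).
    """
    S = np.asarray(condition_cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least two conditions")
    C = _orthonormal_contrast(k)
    M = C @ S @ C.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _effect_epsilon(cells: np.ndarray, shape: tuple[int, ...],
                    effect: tuple[int, ...]) -> float:
    """Box/GG epsilon for one within effect: project the subject x cell
    matrix through the Kronecker product of contrast rows (factors in the
    effect) and averaging rows (factors collapsed over)."""
    mat = np.ones((1, 1))
    rows = 1
    for j, k in enumerate(shape):
        if j in effect:
            block = _orthonormal_contrast(k)
            rows *= k - 1
        else:
            block = np.full((1, k), 1.0 / k)
        mat = np.kron(mat, block)
    if rows == 1:
        return 1.0
    proj = cells.reshape(cells.shape[0], -1) @ mat.T  # subjects x rows
    S = np.cov(proj, rowvar=False)
    S = np.atleast_2d(S)
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (rows * tr2)
    return float(np.clip(eps, 1.0 / rows, 1.0))


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
) -> AnovaResult:
    """Balanced fully-crossed repeated-measures ANOVA.

    ``table`` is long-format with one or more observations per subject x
    cell (replicates are averaged into cell means first). Every within
    effect is tested against its interaction with subject; the adjusted p
    applies the effect's Greenhouse-Geisser epsilon to both degrees of
    freedom. Partial eta squared is SS_effect / (SS_effect + SS_error).
    Unbalanced or missing cells raise rather than impute.
    """
    factors = list(within)
    if not factors:
        raise ValueError("need at least one within factor")
    levels = {f: sorted(table[f].unique()) for f in factors}
    subjects = sorted(table[subject].unique())
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least two subjects")

    cellmeans = table.groupby([subject] + factors, sort=True)[dv].mean()
    shape = tuple(len(levels[f]) for f in factors)
    expected = n * int(np.prod(shape))
    if len(cellmeans) != expected:
        raise ValueError(
            f"design not fully crossed: {len(cellmeans)} cells, "
            f"expected {expected}"
        )
    Y = cellmeans.to_numpy().reshape((n,) + shape)

    grand = Y.mean()
    nf = len(factors)

    def marginal(axes_keep: tuple[int, ...]) -> np.ndarray:
        """Mean over all axes not kept (axis 0 = subject)."""
        axes_all = set(range(Y.ndim))
        out = Y.mean(axis=tuple(sorted(axes_all - set(axes_keep))),
                     keepdims=True)
        return out

    def effect_ss(effect_axes: tuple[int, ...]) -> float:
        """SS via inclusion-exclusion over sub-effects (axis 0 is the
        subject factor; within-factor axes are 1..nf). Broadcasting the
        effect estimate back to the full cell grid makes the sum of squares
        carry the correct replication weight automatically."""
        est = np.zeros((1,) * Y.ndim)
        for r in range(len(effect_axes) + 1):
            for sub in itertools.combinations(effect_axes, r):
                sign = (-1) ** (len(effect_axes) - len(sub))
                est = est + sign * (marginal(sub) - grand)
        return float((np.broadcast_to(est, Y.shape) ** 2).sum())

    results: dict[str, EffectResult] = {}
    for r in range(1, nf + 1):
        for combo in itertools.combinations(range(1, nf + 1), r):
            name = " * ".join(factors[a - 1] for a in combo)
            ss_eff = effect_ss(combo)
            ss_err = effect_ss((0,) + combo)
            df_num = int(np.prod([shape[a - 1] - 1 for a in combo]))
            df_den = df_num * (n - 1)
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            F = ms_eff / ms_err if ms_err > 0 else 0.0
            eps = _effect_epsilon(Y, shape, tuple(a - 1 for a in combo))
            p = float(scipy.stats.f.sf(F, df_num, df_den))
            p_adj = float(scipy.stats.f.sf(F, eps * df_num, eps * df_den))
            peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            results[name] = EffectResult(
                name=name, F=F, df_num=df_num, df_den=df_den, p=p,
                epsilon=eps, p_adjusted=max(p_adj, p), partial_eta_sq=peta,
            )
    return AnovaResult(effects=results, n_subjects=n, factors=levels)


def rm_anova_error_term(
    table: pd.DataFrame, dv: str, factor: str, subject: str = "subject"
) -> tuple[float, int, int]:
    """(MS_error, df_error, n_per_level) of a one-way RM-ANOVA on cell
    means — the error term Tukey HSD uses for that factor's means."""
    cellmeans = table.groupby([subject, factor], sort=True)[dv].mean()
    wide = cellmeans.unstack(factor)
    if wide.isna().any().any():
        raise ValueError("missing cells")
    Y = wide.to_numpy()
    n, k = Y.shape
    resid = Y - Y.mean(0, keepdims=True) - Y.mean(1, keepdims=True) + Y.mean()
    df_err = (n - 1) * (k - 1)
    return float((resid ** 2).sum() / df_err), df_err, n


def tukey_hsd(
    level_means: dict,
    ms_error: float,
    df_error: int,
    n_per_level: int,
) -> PosthocResult:
    """All-pairs Tukey HSD with an externally supplied error term.

    The adjusted p of a pair is the studentized-range tail probability of
    q = |mean difference| / sqrt(MS_error / n) at k levels and df_error
    degrees of freedom.
    """
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    if ms_error <= 0:
        raise ValueError("ms_error must be positive")
    names = list(level_means)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two levels")
    se = np.sqrt(ms_error / n_per_level)
    rows = []
    for a, b in itertools.combinations(names, 2):
        diff = level_means[a] - level_means[b]
        q = abs(diff) / se
        p = float(scipy.stats.studentized_range.sf(q, k, df_error))
        rows.append((a, b, diff, q, min(1.0, p)))
    return PosthocResult(pairs=pd.DataFrame(
        rows, columns=["level_a", "level_b", "mean_diff", "q", "p_adjusted"]
    ))


# --------------------------------------------------------------------------
# the fixed contrast battery
# --------------------------------------------------------------------------

def _is_lateral(mk: MarkerDefinition) -> bool:
    """True when the marker's electrodes are homologous left/right pairs."""
    els = set(mk.electrodes)
    return all(homolog(e) in els and homolog(e) != e for e in els)


def _marker_anova(sub: pd.DataFrame, mk: MarkerDefinition) -> AnovaResult:
    if _is_lateral(mk):
        collapsed = (
            sub.groupby(["subject", "category", "hemisphere"], sort=True)
            ["amplitude_uv"].mean().reset_index()
        )
        return rm_anova(collapsed, "amplitude_uv",
                        ["category", "hemisphere"])
    return rm_anova(sub, "amplitude_uv", ["category", "electrode"])


def _direction_ok(mk: MarkerDefinition, means: dict[str, float]) -> bool:
    sign = -1.0 if mk.polarity == "-" else 1.0
    mag = {c: sign * v for c, v in means.items()}
    for gi in range(len(mk.expected_contrast) - 1):
        for hi in mk.expected_contrast[gi]:
            for lo in mk.expected_contrast[gi + 1]:
                if not mag[hi] > mag[lo]:
                    return False
    return True


def run_paper_contrasts(
    table: pd.DataFrame, alpha: float = 0.01
) -> dict:
    """Run the full per-marker ANOVA battery on a feature table.

    For every marker: a category (x hemisphere or x electrode) RM-ANOVA on
    its analysis categories, Tukey HSD on category means, a verdict on
    whether the category effect is significant at ``alpha`` (GG-adjusted)
    and whether the grand category means reproduce the expected ordering.
    Negative components are compared on magnitude (more negative =
    "larger"). The cross-modal marker is tested as a two-level modality
    effect plus its sign rule; the non-living N170 additionally requires
    the category-by-hemisphere interaction with the word advantage
    confined to the left hemisphere.
    """
    out = {}
    for mk in marker_registry():
        sub = table[
            (table.marker == mk.name)
            & (table.category.isin(mk.analysis_categories))
        ]
        if sub.empty:
            raise ValueError(f"feature table has no rows for {mk.name}")

        if mk.polarity == "modality":
            mod = sub.copy()
            mod["modality"] = [
                "visual" if c in VISUAL_CATEGORIES else "auditory"
                for c in mod.category
            ]
            collapsed = (
                mod.groupby(["subject", "modality", "electrode"], sort=True)
                ["amplitude_uv"].mean().reset_index()
            )
            res = rm_anova(collapsed, "amplitude_uv",
                           ["modality", "electrode"])
            mmeans = collapsed.groupby("modality")["amplitude_uv"].mean()
            direction = (mmeans["visual"] < 0.0) and (mmeans["auditory"] > 0.0)
            eff = res["modality"]
            out[mk.name] = {
                "anova": res,
                "category_effect": eff,
                "means": mmeans.to_dict(),
                "direction_ok": bool(direction),
                "significant": bool(eff.p_adjusted < alpha),
                "recovered": bool(direction and eff.p_adjusted < alpha),
            }
            continue

        res = _marker_anova(sub, mk)
        means = sub.groupby("category")["amplitude_uv"].mean().to_dict()
        eff = res["category"]
        direction = _direction_ok(mk, means)
        significant = eff.p_adjusted < alpha

        ms_err, df_err, n_per = rm_anova_error_term(
            sub, "amplitude_uv", "category"
        )
        posthoc = tukey_hsd(means, ms_err, df_err, n_per)

        entry = {
            "anova": res,
            "category_effect": eff,
            "means": means,
            "posthoc": posthoc,
            "direction_ok": bool(direction),
            "significant": bool(significant),
        }

        if mk.hemisphere_analysis:
            inter = res["category * hemisphere"]
            left = sub[sub.hemisphere == "left"]
            lmeans = left.groupby("category")["amplitude_uv"].mean()
            sign = -1.0 if mk.polarity == "-" else 1.0
            word_left = all(
                sign * lmeans["word_visual"] > sign * lmeans[c]
                for c in ("checkerboard", "object")
            )
            entry["interaction_effect"] = inter
            entry["interaction_significant"] = bool(inter.p_adjusted < alpha)
            entry["word_left_advantage"] = bool(word_left)
            entry["recovered"] = bool(
                direction and significant
                and inter.p_adjusted < alpha and word_left
            )
        else:
            entry["recovered"] = bool(direction and significant)
        out[mk.name] = entry

    out["all_recovered"] = all(
        v["recovered"] for k, v in out.items() if isinstance(v, dict)
    )
    return out
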