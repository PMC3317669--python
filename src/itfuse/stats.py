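"""Repeated-measures ANOVA machinery for between-feature comparisons.

One- or two-way within-subject ANOVA with Greenhouse-Geisser correction of
the degrees of freedom when Mauchly's sphericity test is significant
(alpha = 0.05), followed by uncorrected pairwise comparisons of the
estimated marginal means (least-significant differences).  The model
fitting is delegated to pingouin; this module provides the complete-design
validation, the GG trigger logic and the LSD comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = ["RMDesign", "mauchly_test", "rm_anova_gg", "pairwise_lsd"]

GG_ALPHA = 0.05


@dataclass
class RMDesign:
    """Long-format complete within-subject design.

    ``data`` needs columns ``subject``, the within factor(s), and ``value``.
    """

    data: pd.DataFrame
    factors: tuple[str, ...]
    dv: str = "value"
    subject: str = "subject"

    def __post_init__(self):
        if not 1 <= len(self.factors) <= 2:
            raise ValueError("supported designs have 1 or 2 within factors")
        cols = {self.subject, self.dv, *self.factors}
        missing = cols - set(self.data.columns)
        if missing:
            raise ValueError(f"design table lacks columns {sorted(missing)}")
        counts = self.data.groupby([self.subject, *self.factors], observed=True).size()
        if (counts != 1).any():
            raise ValueError("incomplete design: every subject x cell must appear exactly once")
        n_cells = int(np.prod([self.data[f].nunique() for f in self.factors]))
        per_subject = self.data.groupby(self.subject, observed=True).size()
        if (per_subject != n_cells).any():
            raise ValueError("incomplete design: missing cells for some subjects")

    @classmethod
    def from_wide(cls, values: np.ndarray, factor: str = "level") -> "RMDesign":
        """subjects x levels array -> one-way design."""
        values = np.asarray(values, dtype=float)
        n, k = values.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                factor: np.tile(np.arange(k), n),
                "value": values.ravel(),
            }
        )
        return cls(df, (factor,))

    def n_levels(self, factor: str) -> int:
        return self.data[factor].nunique()


def mauchly_test(design: RMDesign, factor: str | None = None) -> dict:
    """Mauchly's W and its chi-square p-value for a within factor.

    Sphericity concerns the covariance of the k-1 orthonormal contrasts
    among levels; with k = 2 there is only one difference variance and the
    test is undefined (trivially spherical).
    """
    factor = factor or design.factors[0]
    k = design.n_levels(factor)
    if k < 3:
        raise ValueError(
            f"sphericity is trivial for {k} levels: Mauchly's test needs >= 3"
        )
    res = pg.sphericity(
        data=design.data, dv=design.dv, within=factor, subject=design.subject
    )
    return {"W": float(res.W), "chi2": float(res.chi2), "dof": int(res.dof),
            "p": float(res.pval), "spherical": bool(res.spher)}


def rm_anova_gg(design: RMDesign) -> pd.DataFrame:
    """Within-subject F tests, GG-corrected when Mauchly p < 0.05.

    Returns one row per effect with columns ``effect, F, df1, df2, p,
    eps, gg_applied``.  Effects with zero sum of squares report F = 0.
    The GG epsilon always lies in [1/(k-1), 1]; corrected dfs are
    ``eps * df``.
    """
    within = list(design.factors)
    # degenerate design: no variation among cell means -> F = 0 by definition
    cell_means = design.data.groupby(list(design.factors), observed=True)[design.dv].mean()
    if np.allclose(cell_means.to_numpy(), cell_means.to_numpy()[0]):
        n_sub = design.data[design.subject].nunique()
        rows = []
        for effect in within + (["*".join(within)] if len(within) > 1 else []):
            k = int(np.prod([design.data[f].nunique() for f in effect.split("*")]))
            df1 = float(k - 1)
            rows.append({"effect": effect, "F": 0.0, "df1": df1,
                         "df2": float((n_sub - 1) * df1), "p": 1.0, "eps": 1.0,
                         "gg_applied": False})
        return pd.DataFrame(rows)
    res = pg.rm_anova(
        data=design.data,
        dv=design.dv,
        within=within if len(within) > 1 else within[0],
        subject=design.subject,
        correction=True,
        detailed=True,
        effsize="np2",
    )
    res = res[~res["Source"].str.startswith("Error")]
    rows = []
    for _, r in res.iterrows():
        effect = r["Source"]
        if len(within) == 1:
            df1, df2 = float(r["DF"]), float((design.data[design.subject].nunique() - 1) * r["DF"])
        else:
            df1, df2 = float(r["ddof1"]), float(r["ddof2"])
        k_eff = df1 + 1
        eps = float(r["eps"]) if "eps" in r and np.isfinite(r.get("eps", np.nan)) else 1.0
        eps = float(np.clip(eps, 1.0 / max(k_eff - 1, 1), 1.0))

        gg = False
        if k_eff >= 3 and effect in design.factors:
            gg = mauchly_test(design, effect)["p"] < GG_ALPHA
        F = r["F"]
        if not np.isfinite(F):
            F = 0.0 if r["SS"] == 0 else np.nan
        use_df1, use_df2 = (eps * df1, eps * df2) if gg else (df1, df2)
        p = float(sps.f.sf(F, use_df1, use_df2)) if np.isfinite(F) and F > 0 else 1.0
        rows.append(
            {
                "effect": effect,
                "F": float(F),
                "df1": use_df1,
                "df2": use_df2,
                "p": p,
                "eps": eps,
                "gg_applied": gg,
            }
        )
    return pd.DataFrame(rows)


def pairwise_lsd(design: RMDesign, factor: str | None = None) -> pd.DataFrame:
    """Uncorrected pairwise paired-t comparisons of the marginal means (LSD).

    Emits k(k-1)/2 rows with the mean difference, t, df and p per level
    pair.  "Least significant differences" implies no multiplicity
    adjustment; interpret accordingly.
    """
    factor = factor or design.factors[0]
    marg = (
        design.data.groupby([design.subject, factor], observed=True)[design.dv]
        .mean()
        .unstack(factor)
    )
    rows = []
    for a, b in combinations(marg.columns, 2):
        diff = marg[a] - marg[b]
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(marg[a], marg[b])
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": float(diff.mean()),
                "t": float(t),
                "df": len(marg) - 1,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
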