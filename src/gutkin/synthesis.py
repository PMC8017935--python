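"""Combining per-class model fits into headline results.

* random-effects meta-analysis of the per-class slopes of cooperation
  on relatedness (REML estimate of the between-class variance tau^2,
  inverse-variance weights 1/(se^2 + tau^2));
* a joint Wald test on the posterior covariance of a coefficient block
  (used for the reverse-causation check: do the six cooperation
  measures jointly predict relatedness?);
* the infinite-island equilibrium relatedness, the theory curve that
  the Wright-Fisher simulator validates;
* the path summary classifying ecology -> relatedness ->
  cooperation edges as direct, indirect, marginal or absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, DataError, NumericalError

Z975 = 1.959964  # standard normal 97.5% quantile

SIGNIFICANT = 0.05
MARGINAL = 0.10  # 'marginal effect' band: 0.05 <= pMCMC < 0.10


@dataclass
class EffectEstimate:
    """One study-level effect for the meta-analysis.

    The standard error may be given directly (e.g. a posterior SD) or
    recovered from a 95% interval as (upper - lower) / (2 * 1.959964),
    the symmetric normal approximation.
    """

    label: str
    estimate: float
    se: float = None
    ci_lower: float = None
    ci_upper: float = None

    def __post_init__(self):
        if self.se is None:
            if self.ci_lower is None or self.ci_upper is None:
                raise DataError(f"{self.label}: need either se or a CI")
            self.se = (self.ci_upper - self.ci_lower) / (2.0 * Z975)
        if not (self.se > 0):
            raise DataError(f"{self.label}: standard error must be > 0")


@dataclass
class MetaResult:
    """Pooled effect from a random-effects meta-analysis."""

    mean: float
    se: float
    z: float
    ci_lower: float
    ci_upper: float
    p: float
    tau2: float
    method: str
    n_studies: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _reml_tau2(y, v):
    """REML estimate of the between-study variance."""

    def neg_restricted_loglik(tau2):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + np.log(np.sum(w))
            + np.sum(w * (y - mu) ** 2)
        )

    upper = max(10.0 * np.var(y), 1.0)
    res = optimize.minimize_scalar(
        neg_restricted_loglik, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12},
    )
    return max(0.0, float(res.x))


def _dl_tau2(y, v):
    """DerSimonian-Laird moment estimate of the between-study variance."""
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    Q = np.sum(w * (y - mu) ** 2)
    k = len(y)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (Q - (k - 1)) / denom)


def meta_analysis(estimates, method: str = "reml", tau2: float = None) -> MetaResult:
    """Random-effects meta-analysis of per-class slope estimates.

    Each study i contributes its estimate y_i and sampling variance
    se_i^2; the model adds a shared between-study variance tau^2
    (estimated by REML, or DerSimonian-Laird with ``method="dl"``, or
    pinned via ``tau2``). The pooled mean is the inverse-variance
    weighted average with weights 1/(se_i^2 + tau^2).
    """
    if not estimates:
        raise DataError("meta-analysis needs at least one estimate")
    y = np.array([e.estimate for e in estimates], dtype=float)
    v = np.array([e.se for e in estimates], dtype=float) ** 2
    if tau2 is not None:
        t2, method = float(tau2), "fixed-tau2"
    elif len(estimates) == 1:
        t2 = 0.0
    elif method == "reml":
        t2 = _reml_tau2(y, v)
    elif method == "dl":
        t2 = _dl_tau2(y, v)
    else:
        raise DataError(f"unknown tau2 method {method!r}")
    w = 1.0 / (v + t2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = mu / se
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return MetaResult(
        mean=mu,
        se=se,
        z=z,
        ci_lower=mu - Z975 * se,
        ci_upper=mu + Z975 * se,
        p=float(p),
        tau2=t2,
        method=method,
        n_studies=len(estimates),
    )


@dataclass
class WaldResult:
    statistic: float
    df: int
    p: float


def wald_joint_test(b, V, df: int = None) -> WaldResult:
    """Joint Wald test W = b' V^-1 b against chi-square(df).

    ``b`` is the vector of coefficient means and ``V`` their (posterior)
    covariance; ``df`` defaults to len(b).
    """
    b = np.asarray(b, dtype=float).ravel()
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape != (len(b), len(b)):
        raise DataError("b and V dimensions do not agree")
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(
            f"coefficient covariance is singular or ill-conditioned "
            f"(condition number {cond:.3g})"
        )
    df = int(df) if df is not None else len(b)
    W = float(b @ np.linalg.solve(V, b))
    p = float(stats.chi2.sf(W, df))
    return WaldResult(statistic=W, df=df, p=p)


def island_equilibrium_relatedness(deme_size, migration):
    """Equilibrium relatedness of the infinite-island model.

    For haploid demes of size N exchanging migrants at rate m with an
    infinite pool of unrelated immigrants, the identity-by-descent
    probability of two distinct members of a deme satisfies
    ``F = (1-m)^2 (1/N + (1-1/N) F)``, giving

        r = (1 - m)^2 / (N - (N - 1)(1 - m)^2),

    which decreases in both deme size and migration: r = 1 for closed
    demes (m = 0) and r = 0 under full mixing (m = 1).
    """
    N = np.asarray(deme_size, dtype=float)
    m = np.asarray(migration, dtype=float)
    if np.any(N < 1):
        raise DataError("deme size must be >= 1")
    if np.any((m < 0) | (m > 1)):
        raise DataError("migration must be in [0, 1]")
    g = (1.0 - m) ** 2
    out = g / (N - (N - 1.0) * g)
    if out.ndim == 0:
        return float(out)
    return out


def predicted_fold_change(slope: float, r_from: float, r_to: float) -> float:
    """Multiplicative change in expected gene count implied by a
    log-link slope when relatedness moves from ``r_from`` to ``r_to``,
    holding everything else constant: exp(slope * (r_to - r_from))."""
    return float(np.exp(slope * (r_to - r_from)))


# ---------------------------------------------------------------------------
# Path summary
# ---------------------------------------------------------------------------

def _classify(p):
    if p < SIGNIFICANT:
        return "significant"
    if p < MARGINAL:
        return "marginal"
    return "absent"


EDGE_COLUMNS = [
    "source",
    "target",
    "estimate",
    "pmcmc",
    "sign",
    "classification",
    "evidence",
]


@dataclass
class PathSummary:
    """Edge ledger of the path analysis.

    One row per tested edge among {migration, group_size, relatedness,
    cooperation classes}, each tracing to a named fitted coefficient.
    ``slope_stability`` reports, per cooperation class, the relative
    change of the relatedness slope between the relatedness-only model
    and the model that also includes the ecological covariates — the
    'similar effect size' check.
    """

    edges: pd.DataFrame
    slope_stability: pd.DataFrame
    wald: WaldResult
    meta: "MetaResult"
    meta_ecology: "MetaResult" = None

    def write(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def report(self) -> str:
        lines = ["Path analysis summary", "=" * 21, ""]
        lines.append(
            f"Pooled relatedness -> cooperation effect: "
            f"{self.meta.mean:.3f} (SE {self.meta.se:.3f}, z {self.meta.z:.2f})"
        )
        if self.meta_ecology is not None:
            lines.append(
                f"  after ecological controls: {self.meta_ecology.mean:.3f} "
                f"(SE {self.meta_ecology.se:.3f})"
            )
        lines.append(
            f"Reverse causation (cooperation -> relatedness), joint Wald: "
            f"Chi2 = {self.wald.statistic:.2f}, df = {self.wald.df}, "
            f"p = {self.wald.p:.2f}"
        )
        lines.append("")
        letters = "abcdef"
        classes = sorted(
            set(self.edges.loc[self.edges["target"] != "relatedness", "target"])
            - {"relatedness"}
        )
        for letter, cls in zip(letters, classes):
            sub = self.edges[self.edges["target"] == cls]
            parts = []
            for _, row in sub.iterrows():
                parts.append(
                    f"{row['source']}: {row['classification']}"
                    f" ({row['sign']}{abs(row['estimate']):.2f}, p {row['pmcmc']:.3f})"
                )
            lines.append(f"{letter}. {cls}: " + "; ".join(parts))
        for _, row in self.edges[self.edges["target"] == "relatedness"].iterrows():
            lines.append(
                f"{row['source']} -> relatedness: {row['classification']} "
                f"({row['sign']}{abs(row['estimate']):.2f}, p {row['pmcmc']:.3f})"
            )
        return "\n".join(lines)


def path_summary(
    *,
    cooperation_fits: dict,
    cooperation_fits_ecology: dict,
    relatedness_fit,
    relatedness_fit_reverse,
    wald: WaldResult = None,
    meta: MetaResult = None,
    meta_ecology: MetaResult = None,
    relatedness_term: str = "relatedness",
    abundance_term: str = "abundance",
    sporulation_term: str = "sporulation",
) -> PathSummary:
    """Assemble the direct/indirect effect ledger from the fitted models.

    Parameters are the per-class count-model fits without
    (``cooperation_fits``) and with (``cooperation_fits_ecology``)
    ecological covariates, the relatedness model
    (``relatedness_fit``) and its reverse-causation variant with the
    class counts as predictors (``relatedness_fit_reverse``). The Wald
    result and meta-analyses are computed from those fits when not
    supplied. Every edge is classified significant (pMCMC < 0.05),
    marginal (< 0.10) or absent.
    """
    missing = [
        name
        for name, obj in [
            ("cooperation_fits", cooperation_fits),
            ("cooperation_fits_ecology", cooperation_fits_ecology),
            ("relatedness_fit", relatedness_fit),
            ("relatedness_fit_reverse", relatedness_fit_reverse),
        ]
        if not obj
    ]
    if missing:
        raise ConfigurationError(f"path summary missing components: {missing}")
    classes = sorted(cooperation_fits)
    if sorted(cooperation_fits_ecology) != classes:
        raise ConfigurationError(
            "cooperation fit dictionaries cover different classes"
        )

    rows = []

    def add_edge(source, target, fit, term, evidence):
        coef = fit.coefficient(term)
        rows.append(
            (
                source,
                target,
                float(coef["mean"]),
                float(coef["pmcmc"]),
                "+" if coef["mean"] >= 0 else "-",
                _classify(float(coef["pmcmc"])),
                evidence,
            )
        )

    # ecology -> relatedness
    add_edge("migration", "relatedness", relatedness_fit, sporulation_term,
             "relatedness model")
    add_edge("group_size", "relatedness", relatedness_fit, abundance_term,
             "relatedness model")

    # relatedness -> cooperation (with ecological controls) and
    # ecology -> cooperation direct effects
    stability = []
    for cls in classes:
        base = cooperation_fits[cls].coefficient(relatedness_term)
        eco_fit = cooperation_fits_ecology[cls]
        add_edge("relatedness", cls, eco_fit, relatedness_term, "count model + ecology")
        add_edge("migration", cls, eco_fit, sporulation_term, "count model + ecology")
        add_edge("group_size", cls, eco_fit, abundance_term, "count model + ecology")
        eco = eco_fit.coefficient(relatedness_term)
        denom = abs(base["mean"]) if base["mean"] != 0 else np.nan
        stability.append(
            (
                cls,
                float(base["mean"]),
                float(eco["mean"]),
                float((eco["mean"] - base["mean"]) / denom) if denom else np.nan,
            )
        )

    # reverse causation: cooperation -> relatedness
    for cls in classes:
        add_edge(cls, "relatedness", relatedness_fit_reverse, cls, "reverse model")
    if wald is None:
        b = np.array(
            [relatedness_fit_reverse.coefficient(c)["mean"] for c in classes]
        )
        V = relatedness_fit_reverse.vcov(classes)
        wald = wald_joint_test(b, V)

    if meta is None:
        meta = meta_analysis(
            [
                EffectEstimate(
                    label=c,
                    estimate=float(cooperation_fits[c].coefficient(relatedness_term)["mean"]),
                    se=float(np.std(cooperation_fits[c].pooled(relatedness_term), ddof=1)),
                )
                for c in classes
            ]
        )
    if meta_ecology is None:
        meta_ecology = meta_analysis(
            [
                EffectEstimate(
                    label=c,
                    estimate=float(
                        cooperation_fits_ecology[c].coefficient(relatedness_term)["mean"]
                    ),
                    se=float(
                        np.std(cooperation_fits_ecology[c].pooled(relatedness_term), ddof=1)
                    ),
                )
                for c in classes
            ]
        )

    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    stability_df = pd.DataFrame(
        stability,
        columns=["class", "slope_base", "slope_with_ecology", "relative_change"],
    )
    return PathSummary(
        edges=edges,
        slope_stability=stability_df,
        wald=wald,
        meta=meta,
        meta_ecology=meta_ecology,
    )
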