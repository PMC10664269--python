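"""Statistical-genetics layer: HWE, genotype comparisons, genetic models.

Association of a continuous performance outcome with a biallelic genotype is
assessed three ways, mirroring the classic candidate-gene workflow:

* model-free one-way ANOVA across the three genotype groups (with Tukey HSD
  post-hoc and eta^2 = SS_between / SS_total as the genotype variance
  fraction);
* genetic-model correlation: genotypes numerically coded under the additive
  (0, 0.5, 1) or either complete-dominance model (0,0,1 / 0,1,1), r^2 of the
  coded genotype with the outcome expressed as a percentage of the ANOVA
  eta^2 — the model whose percentage is highest is the best-supported mode
  of inheritance;
* carrier grouping t-test (e.g. RR+RX vs XX), Welch by default, with a
  Kolmogorov-Smirnov check of each group against its fitted normal.

Nested Gaussian linear models are compared by likelihood-ratio test, and the
sample-size arithmetic (Monte-Carlo ANOVA power at a Cohen's f, attrition
inflation) lives here too.

For the ACTN3 R577X locus the ACE insertion/deletion coding scheme is
mirrored with X as the loss-of-function allele: RR=0, RX=0.5, XX=1 additive;
"R_dominant" and "X_dominant" are the analogues of the I- and D-dominant
models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DomainError, InputError, ParameterError, ValidationError

#: genotype orderings as (no-effect homozygote, heterozygote, effect homozygote)
LOCUS_GENOTYPES = {
    "ace": ("II", "ID", "DD"),
    "actn3": ("RR", "RX", "XX"),
}

#: numeric codes per model over that ordering
MODEL_CODES = {
    "additive": (0.0, 0.5, 1.0),
    "I_dominant": (0.0, 0.0, 1.0),   # heterozygote behaves like II
    "D_dominant": (0.0, 1.0, 1.0),   # heterozygote behaves like DD
}

_MODEL_ALIASES = {
    "additive": "additive", "add": "additive",
    "i_dominant": "I_dominant", "i_dom": "I_dominant",
    "r_dominant": "I_dominant", "r_dom": "I_dominant",
    "d_dominant": "D_dominant", "d_dom": "D_dominant",
    "x_dominant": "D_dominant", "x_dom": "D_dominant",
}


@dataclass(frozen=True)
class GeneticModelCoding:
    """A named genotype -> numeric code map for one locus."""

    model: str
    locus: str
    code_map: dict

    def code(self, genotypes) -> np.ndarray:
        return code_genetic_model(genotypes, self)


def model_coding(model: str, locus: str = "ace") -> GeneticModelCoding:
    """Build the coding for a model name ('additive', 'I_dominant', ...)."""
    key = _MODEL_ALIASES.get(model.lower().replace("-", "_"))
    if key is None:
        raise ParameterError(f"unknown genetic model {model!r}")
    if locus not in LOCUS_GENOTYPES:
        raise ParameterError(f"unknown locus {locus!r}")
    labels = LOCUS_GENOTYPES[locus]
    return GeneticModelCoding(key, locus, dict(zip(labels, MODEL_CODES[key])))


def code_genetic_model(genotypes, coding: GeneticModelCoding) -> np.ndarray:
    """Map genotype labels to numeric codes under a genetic model."""
    out = np.empty(len(genotypes))
    for i, g in enumerate(genotypes):
        if g not in coding.code_map:
            raise ValidationError(
                f"genotype {g!r} not in {coding.locus} vocabulary "
                f"{tuple(coding.code_map)}"
            )
        out[i] = coding.code_map[g]
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_chi_square(counts) -> tuple[float, int, float]:
    """Pearson chi-square (1 df) of genotype counts against HWE proportions.

    ``counts`` = (hom1, het, hom2).  The allele frequency is estimated from
    the counts themselves; a monomorphic sample fits HWE trivially.
    Invariant under swapping the homozygote labels.
    """
    o = np.asarray(counts, dtype=float)
    if o.shape != (3,) or (o < 0).any():
        raise InputError("counts must be three non-negative genotype counts")
    n = o.sum()
    if n <= 0:
        raise InputError("total genotype count must be positive")
    p = (2 * o[0] + o[1]) / (2 * n)
    q = 1 - p
    e = n * np.array([p**2, 2 * p * q, q**2])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(e > 0, (o - e) ** 2 / e, 0.0)
    chi2 = float(terms.sum())
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# genotype-group comparisons


@dataclass
class AnovaResult:
    F: float
    p: float
    eta_squared: float
    group_stats: pd.DataFrame          # per-genotype n, mean, sd
    tukey: pd.DataFrame                # pairwise comparisons at alpha=0.05


def genotype_anova(values, genotypes, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of an outcome across genotype groups, with Tukey HSD.

    eta^2 is SS_between / SS_total (0 when the data are globally constant).
    Every group must contribute at least two observations.
    """
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    if values.shape != genotypes.shape:
        raise InputError("values and genotypes must align")
    labels, inverse = np.unique(genotypes, return_inverse=True)
    groups = [values[inverse == i] for i in range(len(labels))]
    if len(groups) < 2:
        raise InputError("ANOVA needs at least two genotype groups")
    for lab, grp in zip(labels, groups):
        if len(grp) < 2:
            raise InputError(f"genotype group {lab} has fewer than 2 observations")

    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    if ss_total == 0:
        f_stat, p, eta2 = 0.0, 1.0, 0.0
    else:
        eta2 = ss_between / ss_total
        df_b = len(groups) - 1
        df_w = len(values) - len(groups)
        ss_within = ss_total - ss_between
        if ss_within == 0:
            f_stat, p = math.inf, 0.0
        else:
            f_stat, p = (float(x) for x in stats.f_oneway(*groups))

    gstats = pd.DataFrame({
        "genotype": labels,
        "n": [len(g) for g in groups],
        "mean": [g.mean() for g in groups],
        "sd": [g.std(ddof=1) for g in groups],
    })
    if ss_total > 0 and ss_total != ss_between:
        tk = pairwise_tukeyhsd(values, genotypes, alpha=alpha)
        tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    else:
        tukey = pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj",
                                      "lower", "upper", "reject"])
    return AnovaResult(F=f_stat, p=p, eta_squared=eta2,
                       group_stats=gstats, tukey=tukey)


@dataclass
class TTestResult:
    t: float
    p: float
    n: tuple[int, int]
    means: tuple[float, float]
    ks_normality_p: tuple[float, float]


def dominant_group_ttest(values, genotypes, carrier_genotypes,
                         welch: bool = True) -> TTestResult:
    """Two-sample t-test between allele carriers and non-carriers.

    ``carrier_genotypes`` names the pooled group (e.g. {"RR", "RX"} vs XX, or
    {"DD", "ID"} vs II).  Welch's unequal-variance t by default; each group
    also gets a one-sample Kolmogorov-Smirnov test against the normal fitted
    to it (a normality screen, not a gatekeeper).
    """
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    mask = np.isin(genotypes, list(carrier_genotypes))
    a, b = values[mask], values[~mask]
    if len(a) < 2 or len(b) < 2:
        raise InputError("both genotype groups need at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)

    def ks(x) -> float:
        sd = x.std(ddof=1)
        if sd == 0:
            return 0.0
        return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)

    return TTestResult(t=float(t), p=float(p), n=(len(a), len(b)),
                       means=(float(a.mean()), float(b.mean())),
                       ks_normality_p=(ks(a), ks(b)))


# ---------------------------------------------------------------------------
# genetic-model variance decomposition


@dataclass
class ModelVarianceResult:
    eta_squared: float
    r_squared: dict            # model name -> r^2 of coded genotype vs outcome
    percent_of_anova: dict     # model name -> 100 * r^2 / eta^2
    best_model: str


def model_variance_percent(values, genotypes, locus: str = "ace",
                           models=("additive", "I_dominant", "D_dominant"),
                           ) -> ModelVarianceResult:
    """Percent of the ANOVA-explained variance captured by each genetic model.

    Per model, r^2 is the squared Pearson correlation between the coded
    genotype and the outcome, expressed as ``100 * r^2 / eta^2``; the model
    with the highest percentage is reported best (ties break toward the
    additive model).  Undefined when the model-free ANOVA explains nothing.
    """
    anova = genotype_anova(values, genotypes)
    if anova.eta_squared <= 0:
        raise DomainError("eta^2 is zero: percent of explained variance undefined")
    values = np.asarray(values, dtype=float)
    r2: dict[str, float] = {}
    for m in models:
        coding = model_coding(m, locus)
        codes = code_genetic_model(genotypes, coding)
        if np.ptp(codes) == 0:
            r2[coding.model] = 0.0
            continue
        r = np.corrcoef(codes, values)[0, 1]
        r2[coding.model] = float(r**2)
    percent = {m: 100.0 * v / anova.eta_squared for m, v in r2.items()}
    best = max(sorted(percent, key=lambda m: m != "additive"),
               key=lambda m: percent[m])
    return ModelVarianceResult(eta_squared=anova.eta_squared, r_squared=r2,
                               percent_of_anova=percent, best_model=best)


# ---------------------------------------------------------------------------
# likelihood-ratio covariate test


@dataclass
class LRTResult:
    lr: float
    df: int
    p: float


def lrt_covariate(data: pd.DataFrame, outcome: str,
                  full_covariates, dropped) -> LRTResult:
    """Likelihood-ratio test for dropping covariate(s) from a Gaussian OLS.

    The full model regresses ``outcome`` on all ``full_covariates`` (plus an
    intercept); the null model omits ``dropped``.  LR = 2 (llf_full -
    llf_null) with a chi-square reference on the number of dropped columns.
    """
    if isinstance(dropped, str):
        dropped = [dropped]
    full_covariates = list(full_covariates)
    missing = [c for c in dropped if c not in full_covariates]
    if missing:
        raise InputError(f"null model is not nested: {missing} not in the full model")
    null_covariates = [c for c in full_covariates if c not in dropped]
    y = np.asarray(data[outcome], dtype=float)

    def fit(cols):
        X = sm.add_constant(np.asarray(data[cols], dtype=float)) if cols \
            else np.ones((len(y), 1))
        return sm.OLS(y, X).fit()

    full = fit(full_covariates)
    null = fit(null_covariates)
    lr = 2.0 * (full.llf - null.llf)
    lr = max(lr, 0.0)
    df = len(dropped)
    return LRTResult(lr=float(lr), df=df, p=float(stats.chi2.sf(lr, df)))


# ---------------------------------------------------------------------------
# sample-size arithmetic


def attrition_adjusted_n(base_n: int, dropout_rate: float) -> int:
    """Inflate a planned sample size for expected attrition (ceil)."""
    if not 0 <= dropout_rate < 1:
        raise ParameterError("dropout rate must be in [0, 1)")
    if base_n <= 0:
        raise ParameterError("base sample size must be positive")
    return math.ceil(base_n * (1 + dropout_rate))


def balanced_allocation(total_n: int, k: int) -> list[int]:
    """Split total_n over k groups; the remainder goes to the first groups."""
    base, rem = divmod(total_n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def cohens_f_means(k: int, cohen_f: float, sizes=None) -> np.ndarray:
    """Equally spaced group means realising Cohen's f at unit within-group sd.

    The (size-weighted) standard deviation of the returned means equals
    ``cohen_f`` exactly, so the noncentrality of the one-way ANOVA is
    ``f^2 * N``.
    """
    u = np.arange(k, dtype=float)
    w = np.ones(k) / k if sizes is None else np.asarray(sizes, float) / np.sum(sizes)
    uc = u - w @ u
    sd_w = math.sqrt(float(w @ uc**2))
    if sd_w == 0:
        return np.zeros(k)
    return cohen_f / sd_w * uc


def empirical_power_oneway(k: int, total_n: int, cohen_f: float,
                           alpha: float = 0.05, reps: int = 1000,
                           seed: int = 0) -> float:
    """Monte-Carlo power of a balanced one-way ANOVA at effect size Cohen's f.

    Group means are spaced to realise ``cohen_f`` with unit within-group sd;
    the estimate is the fraction of replicates rejecting at ``alpha``.
    """
    if k < 2:
        raise ParameterError("need at least two groups")
    if total_n < 2 * k:
        raise ParameterError("need at least two observations per group")
    if cohen_f < 0 or not 0 < alpha < 1 or reps < 1:
        raise ParameterError("invalid cohen_f, alpha or reps")
    sizes = balanced_allocation(total_n, k)
    means = cohens_f_means(k, cohen_f, sizes)
    rng = np.random.default_rng(seed)
    groups = [rng.normal(mu, 1.0, size=(reps, n)) for mu, n in zip(means, sizes)]
    res = stats.f_oneway(*groups, axis=1)
    return float(np.mean(res.pvalue < alpha))
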