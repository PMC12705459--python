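"""Group statistics: two-way ANCOVA with interaction terms and partial
eta-squared, within-sex post-hoc t-tests with Cohen's d, Spearman
correlations against family-history density, and Benjamini-Hochberg FDR.

Conventions pinned here (documented, not inferred from any source): Type
III sums of squares with sum-to-zero contrasts for categorical factors,
classic pooled-variance t-tests (Welch behind a flag), listwise deletion
of incomplete rows with a logged count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.linalg import qr
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from brainte.cohort import FH_MIXED, FH_NEG, FH_POS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Term layout for the two-way ANCOVA on one TE outcome."""

    outcome: str
    factors: tuple[str, ...] = ("sex", "fh_group")
    categorical_covariates: tuple[str, ...] = ("race_ethnicity", "scanner_model")
    continuous_covariates: tuple[str, ...] = (
        "age_months",
        "income_level",
        "parental_education",
        "parental_mental_health",
        "prenatal_exposure",
        "mean_fd",
        "puberty_stage",
    )
    interactions: tuple[tuple[str, str], ...] = (
        ("sex", "fh_group"),
        ("sex", "puberty_stage"),
        ("fh_group", "income_level"),
    )

    @property
    def columns(self) -> tuple[str, ...]:
        cols = {self.outcome, *self.factors, *self.categorical_covariates, *self.continuous_covariates}
        for a, b in self.interactions:
            cols.update((a, b))
        return tuple(cols)

    def _term(self, name: str) -> str:
        if name in self.factors or name in self.categorical_covariates:
            return f"C({name}, Sum)"
        return name

    def formula(self) -> str:
        terms = [self._term(f) for f in self.factors]
        terms += [self._term(c) for c in self.categorical_covariates]
        terms += list(self.continuous_covariates)
        terms += [f"{self._term(a)}:{self._term(b)}" for a, b in self.interactions]
        return f"Q('{self.outcome}') ~ " + " + ".join(terms)


@dataclass(frozen=True)
class AncovaResult:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    p_fdr: float | None = None


@dataclass(frozen=True)
class PosthocResult:
    contrast: str
    t: float
    p: float
    cohens_d: float
    n_per_group: tuple[int, int]


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    spearman_rho: float
    p: float
    n: int
    stratum: str = "all"


_TERM_RE = re.compile(r"C\(([^,)]+), Sum\)")


def _friendly_term(term: str) -> str:
    return _TERM_RE.sub(r"\1", term)


def fit_ancova(data: pd.DataFrame, spec: ModelSpec) -> list[AncovaResult]:
    """Two-way ANCOVA (Type III SS, sum-to-zero contrasts) for one outcome.

    FH+/- subjects are excluded from this categorical model; rows with any
    missing value among the model columns are dropped with a logged count.
    A constant outcome yields degenerate all-zero F results with a warning.
    """
    cols = [c for c in spec.columns if c in data.columns]
    missing_cols = set(spec.columns) - set(cols)
    if missing_cols:
        raise ValueError(f"data missing model columns: {sorted(missing_cols)}")
    df = data.loc[data["fh_group"] != FH_MIXED, list(spec.columns)].copy()
    n_before = len(df)
    df = df.dropna()
    dropped = n_before - len(df)
    if dropped:
        logger.warning("fit_ancova: dropped %d row(s) with missing values", dropped)
    cell_counts = df.groupby(["sex", "fh_group"], observed=True).size()
    if len(cell_counts) < 4 or (cell_counts < 2).any():
        raise ValueError(f"need >=2 subjects per sex x FH cell; got\n{cell_counts}")

    y = df[spec.outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        logger.warning("fit_ancova: outcome %r is constant; degenerate model", spec.outcome)
        terms = [_friendly_term(t) for t in spec.formula().split("~")[1].split("+")]
        return [
            AncovaResult(term=t.strip(), F=0.0, df_num=1, df_den=max(len(df) - 2, 1), p=1.0, partial_eta_sq=0.0)
            for t in terms
        ]

    model = smf.ols(spec.formula(), data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("model has no residual degrees of freedom")
    exog = model.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = model.model.exog_names
        _, r, piv = qr(exog, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(exog.shape) * np.finfo(float).eps
        aliased = sorted(names[j] for j in piv[np.abs(np.diag(r)) <= tol])
        raise ValueError(f"rank-deficient design (rank {rank} < {len(names)}); aliased: {aliased}")
    table = anova_lm(model, typ=3)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_den = int(table.loc["Residual", "df"])
    results = []
    for term, row in table.iterrows():
        if term in ("Intercept", "Residual"):
            continue
        ss = float(row["sum_sq"])
        results.append(
            AncovaResult(
                term=_friendly_term(str(term)),
                F=float(row["F"]),
                df_num=int(row["df"]),
                df_den=df_den,
                p=float(row["PR(>F)"]),
                partial_eta_sq=ss / (ss + ss_err),
            )
        )
    return results


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / pooled)


def posthoc_ttest(
    data: pd.DataFrame, outcome: str, welch: bool = False, contrast_label: str = "FH+ vs FH-"
) -> PosthocResult:
    """Unpaired two-sided t-test of FH+ minus FH- on ``outcome``."""
    a = data.loc[data["fh_group"] == FH_POS, outcome].dropna().to_numpy(dtype=float)
    b = data.loc[data["fh_group"] == FH_NEG, outcome].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"each group needs >=2 subjects (got {len(a)} FH+, {len(b)} FH-)")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return PosthocResult(
        contrast=contrast_label,
        t=float(t),
        p=float(p),
        cohens_d=_cohens_d(a, b),
        n_per_group=(len(a), len(b)),
    )


def posthoc_within_sex(
    data: pd.DataFrame, outcome: str, welch: bool = False
) -> dict[str, PosthocResult]:
    """FH+ vs FH- t-test within each sex separately."""
    out = {}
    for sex in ("female", "male"):
        sub = data[data["sex"] == sex]
        out[sex] = posthoc_ttest(
            sub, outcome, welch=welch, contrast_label=f"FH+ vs FH- within {sex}"
        )
    return out


def spearman_fhd(
    data: pd.DataFrame, outcome: str, stratify_by_sex: bool = False, against: str = "fhd"
) -> list[CorrelationResult]:
    """Spearman rank correlation of ``outcome`` against FHD (all three FH
    groups included), optionally within each sex."""
    strata = [("all", data)]
    if stratify_by_sex:
        strata = [(s, data[data["sex"] == s]) for s in ("female", "male")]
    results = []
    for name, sub in strata:
        pair = sub[[against, outcome]].dropna()
        if len(pair) < 3:
            raise ValueError(f"stratum {name!r} has fewer than 3 complete observations")
        y = pair[outcome].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError(f"outcome {outcome!r} is constant in stratum {name!r}; rho undefined")
        rho, p = sps.spearmanr(pair[against], pair[outcome])
        results.append(
            CorrelationResult(
                variable_pair=(against, outcome),
                spearman_rho=float(rho),
                p=float(p),
                n=len(pair),
                stratum=name,
            )
        )
    return results


def bh_fdr(
    p_values: np.ndarray | list[float],
    q: float = 0.05,
    family: np.ndarray | list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up within each family.

    Returns (adjusted p-values, rejection flags) in the input order; with
    ``family=None`` all p-values form a single family.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.empty_like(p)
    reject = np.zeros(p.shape, dtype=bool)
    fam = np.zeros(p.shape) if family is None else np.asarray(family)
    for value in pd.unique(fam):
        idx = np.flatnonzero(fam == value)
        rej, adj, _, _ = multipletests(p[idx], alpha=q, method="fdr_bh")
        adjusted[idx] = adj
        reject[idx] = rej
    return adjusted, reject


def ancova_to_frame(results: dict[str, list[AncovaResult]], level: str = "") -> pd.DataFrame:
    """Tidy table of ANCOVA results keyed by outcome."""
    rows = []
    for outcome, terms in results.items():
        for r in terms:
            rows.append(
                {
                    "level": level,
                    "outcome": outcome,
                    "term": r.term,
                    "F": r.F,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "p": r.p,
                    "partial_eta_sq": r.partial_eta_sq,
                    "p_fdr": r.p_fdr,
                }
            )
    return pd.DataFrame(rows)


def run_group_stats(
    te_wide: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: dict[str, list[str]],
    q: float = 0.05,
    welch: bool = False,
) -> dict[str, pd.DataFrame]:
    """ANCOVA + FDR + post-hoc + Spearman over families of TE outcomes.

    ``outcomes`` maps a family name (e.g. 'global', 'network') to the TE
    columns tested in that family; BH-FDR on the sex:fh_group interaction
    p-value is applied within each family.
    """
    data = covariates.merge(te_wide, on="subject_id", validate="one_to_one")
    ancova_rows = []
    posthoc_rows = []
    spearman_rows = []
    for family, cols in outcomes.items():
        fam_results: dict[str, list[AncovaResult]] = {}
        for col in cols:
            fam_results[col] = fit_ancova(data, ModelSpec(outcome=col))
        frame = ancova_to_frame(fam_results, level=family)
        # FDR within family, separately per model term
        frame["p_fdr"] = np.nan
        for term in frame["term"].unique():
            mask = frame["term"] == term
            adj, _ = bh_fdr(frame.loc[mask, "p"].to_numpy(), q=q)
            frame.loc[mask, "p_fdr"] = adj
        ancova_rows.append(frame)
        cat = data[data["fh_group"] != FH_MIXED]
        for col in cols:
            for sex, res in posthoc_within_sex(cat, col, welch=welch).items():
                posthoc_rows.append(
                    {
                        "level": family,
                        "outcome": col,
                        "sex": sex,
                        "contrast": res.contrast,
                        "t": res.t,
                        "p": res.p,
                        "cohens_d": res.cohens_d,
                        "n_fh_pos": res.n_per_group[0],
                        "n_fh_neg": res.n_per_group[1],
                    }
                )
            for res in spearman_fhd(data, col, stratify_by_sex=True):
                spearman_rows.append(
                    {
                        "level": family,
                        "outcome": col,
                        "stratum": res.stratum,
                        "spearman_rho": res.spearman_rho,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    return {
        "ancova": pd.concat(ancova_rows, ignore_index=True),
        "posthoc": pd.DataFrame(posthoc_rows),
        "spearman": pd.DataFrame(spearman_rows),
    }
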