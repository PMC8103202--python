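"""Repertoire frequency tables and hypothesis tests.

Frequency tables pool hybridomas within a stratum (strain x age x isotype by
default), with denominators counting tested antibodies only.  Proportions of
categorical outcomes across strata are compared by Pearson's chi-square test
(no continuity correction by default; Yates optional), and heavy-chain
amino-acid replacement loads by an unpaired two-sided t test (pooled
variance by default; Welch optional).  No multiple-testing correction is
applied by default; Benjamini-Hochberg is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from polyrep.reactivity import CATEGORIES


@dataclass
class TestResult:
    __test__ = False  # not a pytest collection target

    test: str  # "chi-square" | "t-test"
    statistic: float
    df: float
    pvalue: float
    details: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic, "df": self.df,
            "pvalue": self.pvalue, "warnings": list(self.warnings),
            **{k: v for k, v in self.details.items()
               if isinstance(v, (int, float, str, list))},
        }


def tabulate(
    profiles: pd.DataFrame,
    *,
    by: tuple[str, ...] = ("strain", "age_weeks", "isotype"),
    category_col: str = "category",
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Per-stratum counts and proportions of a categorical column.

    Rows with category ``"not-tested"`` are excluded from the denominator.
    Empty strata are emitted with denominator 0 and flagged.  The table is
    invariant to input row order.
    """
    if category_col not in profiles.columns:
        raise ValueError(f"missing category column {category_col!r}")
    df = profiles[profiles[category_col].isin(categories)]
    rows = []
    for key, grp in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        counts = grp[category_col].value_counts()
        denom = int(counts.sum())
        row = dict(zip(by, key))
        row["denominator"] = denom
        for cat in categories:
            n = int(counts.get(cat, 0))
            row[f"n_{cat}"] = n
            row[f"p_{cat}"] = n / denom if denom else np.nan
        row["defined"] = denom > 0
        rows.append(row)
    return pd.DataFrame(rows)


def chi_square(table, *, yates: bool = False) -> TestResult:
    """Pearson chi-square test of homogeneity on a 2D contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("contingency table must hold non-negative integer counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total: test undefined")
    res = sps.chi2_contingency(obs, correction=yates)
    warnings = []
    if (res.expected_freq < 5).any():
        warnings.append("expected count < 5 in at least one cell; "
                        "asymptotic p-value may be inaccurate")
    return TestResult(
        test="chi-square", statistic=float(res.statistic), df=float(res.dof),
        pvalue=float(res.pvalue),
        details={"observed": obs.tolist(), "expected": res.expected_freq.tolist(),
                 "yates": yates},
        warnings=warnings,
    )


def t_test_mutations(group_a, group_b, *, equal_var: bool = True) -> TestResult:
    """Unpaired two-sided t test on per-antibody mutation counts."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    details = {
        "n_a": int(len(a)), "n_b": int(len(b)),
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)), "sd_b": float(b.std(ddof=1)),
        "equal_var": equal_var,
    }
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult("t-test", 0.0, float(len(a) + len(b) - 2), 1.0,
                              details, ["zero variance in both groups; p = 1 by convention"])
        return TestResult("t-test", np.inf, float(len(a) + len(b) - 2), 0.0,
                          details, ["zero variance in both groups with unequal means"])
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult("t-test", float(res.statistic), float(res.df),
                      float(res.pvalue), details)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (off by default in all pipelines; opt-in)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def summarize_cdr3(
    annotations: pd.DataFrame,
    *,
    length_col: str = "heavy_cdr3_length",
    by: tuple[str, ...] = ("strain", "age_weeks", "isotype"),
) -> pd.DataFrame:
    """Min/max/mean/median CDR3 length per stratum (undefined strata flagged)."""
    df = annotations.copy()
    df[length_col] = pd.to_numeric(df[length_col], errors="coerce")
    keys = [c for c in by if c in df.columns]
    rows = []
    grouped = df.groupby(keys, sort=True, dropna=False) if keys else [((), df)]
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        lengths = grp[length_col].dropna()
        row = dict(zip(keys, key))
        row["n"] = int(len(lengths))
        if len(lengths):
            row.update(min=int(lengths.min()), max=int(lengths.max()),
                       mean=float(lengths.mean()), median=float(lengths.median()))
            row["defined"] = True
        else:
            row.update(min=pd.NA, max=pd.NA, mean=np.nan, median=np.nan, defined=False)
        rows.append(row)
    return pd.DataFrame(rows)


SUBCLASSES = ("IgG1", "IgG2b", "IgG2c", "IgG3")


def subclass_distribution(records: pd.DataFrame, *, by: tuple[str, ...] = ("strain",),
                          subclass_col: str = "subclass") -> pd.DataFrame:
    """IgG subclass frequency vector per stratum; frequencies sum to 1."""
    df = records[records[subclass_col].astype(str).str.len() > 0]
    unknown = sorted(set(df[subclass_col]) - set(SUBCLASSES))
    if unknown:
        raise ValueError(f"unknown subclass labels: {unknown}")
    rows = []
    for key, grp in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        counts = grp[subclass_col].value_counts()
        total = int(counts.sum())
        row = dict(zip(by, key))
        row["n"] = total
        for sc in SUBCLASSES:
            row[f"freq_{sc}"] = int(counts.get(sc, 0)) / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def category_chi_square_by_strain(
    freq: pd.DataFrame,
    *,
    categories: tuple[str, ...] = CATEGORIES,
) -> list[dict]:
    """Strain-vs-strain chi-square at each (age rank, isotype) stratum pair.

    Ages differ slightly between strains (e.g. 28/47/66 vs 26/47/69 weeks),
    so strata are matched by age rank within strain.  Also emits the
    age-trend comparison within each strain x isotype.  Returns a list of
    JSON-ready dicts.
    """
    out = []
    df = freq.copy()
    df["age_rank"] = df.groupby(["strain", "isotype"])["age_weeks"].rank(method="dense")
    for (rank, iso), grp in df.groupby(["age_rank", "isotype"]):
        if grp["strain"].nunique() < 2:
            continue
        tab = grp.set_index("strain")[[f"n_{c}" for c in categories]]
        try:
            res = chi_square(tab.to_numpy())
        except ValueError:
            continue
        out.append({"comparison": "between-strains", "age_rank": int(rank),
                    "isotype": iso, "strains": list(tab.index),
                    **res.as_dict()})
    for (strain, iso), grp in df.groupby(["strain", "isotype"]):
        if len(grp) < 2:
            continue
        tab = grp.set_index("age_weeks")[[f"n_{c}" for c in categories]]
        try:
            res = chi_square(tab.to_numpy())
        except ValueError:
            continue
        out.append({"comparison": "across-ages", "strain": strain, "isotype": iso,
                    "ages": [int(a) for a in tab.index], **res.as_dict()})
    return out
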