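"""Segregation and phenotype statistics.

Covers the classical genetics read-outs of a recessive-mutant cross:
a Pearson chi-square goodness-of-fit test against a 3:1 phenotype ratio,
two-group t tests on quantitative traits (Fv/Fm, SPAD, pigment levels),
percent-of-control summaries of a pigment table and chlorophyll a/b
ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Published HPLC pigment means and standard deviations (pmol per mg leaf
#: fresh weight, n = 3 biological replicates) for the wild-type-like
#: sibling line (control) and the pale-green chli missense mutant.
#: Columns: neoxanthin, lutein, chlorophyll b, chlorophyll a, beta-carotene,
#: VAZ (violaxanthin+antheraxanthin+zeaxanthin) and total chlorophyll.
REFERENCE_PIGMENTS = pd.DataFrame(
    {
        "Nx": [62, 34],
        "Lut": [189, 103],
        "Chl_b": [478, 235],
        "Chl_a": [1563, 930],
        "beta_Car": [182, 117],
        "VAZ": [120, 104],
        "Chl_total": [2041, 1164],
    },
    index=["Xan-h", "xan-h.chli-1"],
)

REFERENCE_PIGMENT_SD = pd.DataFrame(
    {
        "Nx": [11, 9],
        "Lut": [29, 30],
        "Chl_b": [101, 52],
        "Chl_a": [302, 203],
        "beta_Car": [44, 30],
        "VAZ": [20, 25],
        "Chl_total": [402, 255],
    },
    index=["Xan-h", "xan-h.chli-1"],
)


@dataclass(frozen=True)
class SegregationCount:
    """Observed phenotype-class counts and the Mendelian expectation."""

    n_wt: int
    n_mut: int
    expected_ratio: tuple[float, float] = (3, 1)

    def __post_init__(self) -> None:
        if self.n_wt < 0 or self.n_mut < 0:
            raise ValueError("counts must be non-negative")
        if min(self.expected_ratio) <= 0:
            raise ValueError("ratio parts must be positive")

    @property
    def total(self) -> int:
        return self.n_wt + self.n_mut


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p_value: float
    expected: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def chisq_segregation(
    counts: SegregationCount, continuity_correction: bool = False
) -> ChisqResult:
    """Pearson goodness-of-fit test of observed counts against the ratio.

    For the default 3:1 ratio the expectations are 3/4 and 1/4 of the
    total.  No continuity correction by default (plain Pearson is the
    convention for segregation tests); Yates is available behind the
    flag for comparison.
    """
    total = counts.total
    if total == 0:
        raise ValueError("zero total count")
    wt_parts, mut_parts = counts.expected_ratio
    parts = wt_parts + mut_parts
    expected = (total * wt_parts / parts, total * mut_parts / parts)
    observed = (counts.n_wt, counts.n_mut)
    if continuity_correction:
        statistic = sum(
            (abs(o - e) - 0.5) ** 2 / e for o, e in zip(observed, expected)
        )
    else:
        statistic = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    df = 1
    p = float(sps.chi2.sf(statistic, df))
    return ChisqResult(statistic=float(statistic), df=df, p_value=p, expected=expected)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    variant: str


def two_group_t(
    values_a, values_b, variant: str = "student"
) -> TTestResult:
    """Two-sided two-sample t test.

    ``variant="student"`` uses the pooled-variance test (the classical
    "Student's t-test"); ``"welch"`` uses the Satterthwaite
    approximation.  Degenerate zero-variance input with unequal means is
    reported as p -> 0 with a warning rather than an error, because
    simulator configurations with sd = 0 are legal.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in {"student", "welch"}:
        raise ValueError("variant must be 'student' or 'welch'")

    if np.ptp(a) == 0 and np.ptp(b) == 0:  # constant groups (exact)
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p_value=1.0, variant=variant)
        warnings.warn(
            "zero pooled variance with unequal means: p reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return TTestResult(t=float("inf"), df=df, p_value=0.0, variant=variant)

    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    df = float(res.df)
    return TTestResult(
        t=float(res.statistic), df=df, p_value=float(res.pvalue), variant=variant
    )


@dataclass
class PigmentTable:
    """Pigment quantification table: one row per genotype, one column per
    pigment, values are means over replicates (pmol per mg fresh weight).

    ``sd`` and ``n_replicates`` are optional side tables with the same
    shape / index.
    """

    means: pd.DataFrame
    sd: pd.DataFrame | None = None
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        if (self.means < 0).any().any():
            raise ValueError("pigment means must be non-negative")

    @classmethod
    def reference(cls) -> "PigmentTable":
        """The bundled published pigment table (two genotypes, n = 3)."""
        return cls(
            means=REFERENCE_PIGMENTS.astype(float),
            sd=REFERENCE_PIGMENT_SD.astype(float),
            n_replicates=3,
        )

    @classmethod
    def from_csv(cls, path) -> "PigmentTable":
        return cls(means=pd.read_csv(path, index_col=0))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_of_control(
    table: PigmentTable, control: str, test: str
) -> pd.DataFrame:
    """Per-pigment percentages of the test genotype relative to control.

    Returns a frame with the unrounded percentage and its half-up
    integer rounding.  Columns whose control mean is zero come out NA.
    """
    for row in (control, test):
        if row not in table.means.index:
            raise KeyError(f"genotype {row!r} not in table")
    ctrl = table.means.loc[control]
    tst = table.means.loc[test]
    pct = 100.0 * tst / ctrl.where(ctrl != 0)
    rounded = pct.map(lambda v: round_half_up(v) if pd.notna(v) else np.nan)
    return pd.DataFrame({"percent": pct, "percent_rounded": rounded})


def chl_ratio(
    table: PigmentTable,
    genotype: str,
    replicates: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Chlorophyll a / chlorophyll b ratio for one genotype.

    The headline value is the ratio of the column means.  When
    per-replicate values are supplied (columns ``Chl_a`` and ``Chl_b``,
    one row per replicate), the mean and sd of per-replicate ratios are
    also reported — table values published as "mean +/- sd of replicate
    ratios" match that variant, not the ratio of rounded means.
    """
    row = table.means.loc[genotype]
    if row["Chl_b"] <= 0:
        raise ValueError("Chl_b must be positive for a ratio")
    out = {"ratio_of_means": float(row["Chl_a"] / row["Chl_b"])}
    if replicates is not None:
        per_rep = replicates["Chl_a"] / replicates["Chl_b"]
        out["replicate_ratio_mean"] = float(per_rep.mean())
        out["replicate_ratio_sd"] = float(per_rep.std(ddof=1))
    return out
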