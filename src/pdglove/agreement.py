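"""Clinical agreement statistics: Cohen's kappa with Z-score, and ICC.

Cohen's kappa measures chance-corrected agreement between the glove's
grades and the clinician's grades on the same subjects.  Significance
uses the large-sample Z statistic under the null of independent raters
(the form SPSS reports):

    kappa = (po - pe) / (1 - pe)
    Var0  = [pe + pe^2 - sum_i pi+ p+i (pi+ + p+i)] / (n (1 - pe)^2)
    Z     = kappa / sqrt(Var0)

Test-retest reliability uses the intraclass correlation coefficient;
the default variant is two-way, absolute-agreement, single-measurement
(the ICC(A,1) mean-squares form, appropriate for a fixed device rated
repeatedly on each subject), with an F-distribution 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

KAPPA_BANDS = ((0.8, "excellent"), (0.6, "good"), (0.4, "moderate"))
ICC_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


def _band(value: float, cuts) -> str:
    for lo, name in cuts:
        if value > lo:
            return name
    return "poor"


@dataclass
class ContingencyTable:
    """R x R cross-tabulation; rows = system grades, columns = clinician grades."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        r = len(self.labels)
        if self.counts.shape != (r, r):
            raise ValueError(f"counts must be {r}x{r} to match the labels")
        if (self.counts < 0).any() or self.counts.sum() < 1:
            raise ValueError("counts must be non-negative with total >= 1")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, rater_a, rater_b) -> "ContingencyTable":
        a = np.asarray(rater_a)
        b = np.asarray(rater_b)
        if a.shape != b.shape:
            raise ValueError("raters must grade the same items")
        labels = sorted(set(a) | set(b), key=str)
        pos = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for xa, xb in zip(a, b):
            counts[pos[xa], pos[xb]] += 1
        return cls(labels=[str(lab) for lab in labels], counts=counts)


@dataclass
class KappaResult:
    kappa: float
    z: float
    p_value: float
    band: str


def cohen_kappa(table: ContingencyTable) -> KappaResult:
    """Cohen's kappa with large-sample null-variance Z and two-sided p."""
    counts = table.counts
    n = table.n
    if n < 2:
        raise ValueError("need at least two graded items")
    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if pe >= 1.0:
        raise ValueError("kappa undefined: both raters use a single category")
    kappa = (po - pe) / (1 - pe)
    var0 = (pe + pe**2 - float(np.sum(row * col * (row + col)))) / (n * (1 - pe) ** 2)
    z = kappa / np.sqrt(var0)
    p_value = 2 * (1 - stats.norm.cdf(abs(z)))
    return KappaResult(kappa=float(kappa), z=float(z), p_value=float(p_value),
                       band=_band(kappa, KAPPA_BANDS))


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    band: str


def icc(data, model: str = "ICC2", ci_level: float = 0.95) -> ICCResult:
    """Intraclass correlation from a subjects x repeated-measurements matrix.

    ``model`` selects among the six standard single/average-measurement
    variants ('ICC1', 'ICC2', 'ICC3', 'ICC1k', 'ICC2k', 'ICC3k').  The
    default ICC2 is the absolute-agreement single-measurement form,
    whose point estimate is identical for the two-way random and
    two-way mixed designs.
    """
    mat = np.asarray(data, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need >= 2 subjects with >= 2 measurements each")
    if not np.all(np.isfinite(mat)):
        raise ValueError("measurements must be finite (balanced design, no NaN)")
    if np.ptp(mat) == 0:
        raise ValueError("ICC undefined: all measurements identical")
    n_subj, n_meas = mat.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), n_meas),
        "measurement": np.tile(np.arange(n_meas), n_subj),
        "value": mat.ravel(),
    })
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="measurement", ratings="value"
    ).set_index("Type")
    aliases = {
        "ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
        "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)",
    }
    key = aliases.get(model, model)
    if key not in table.index:
        raise ValueError(
            f"unknown ICC variant {model!r}; use one of {sorted(aliases)} or {list(table.index)}"
        )
    row = table.loc[key]
    value = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    if abs(ci_level - 0.95) > 1e-9:
        raise NotImplementedError("only the 95% confidence interval is exposed")
    return ICCResult(icc=value, ci95=(lo, hi), band=_band(value, ICC_BANDS))
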