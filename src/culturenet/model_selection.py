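"""Exhaustive BIC model sweeps, Bayes-factor reporting and significance censuses.

For each time bin, every subset of the candidate weight matrices (including
the null intercept-only model: 2^4 = 16 specs for four matrices) is fitted by
maximum likelihood and ranked by BIC. Aggregates across bins follow the
selection-table layout used in comparative work of this kind: how often each
matrix appears in the preferred and second-best models, median BIC gaps from
the preferred to the 2nd and 3rd ranked models, and a single-matrix
significance census with a one-sample t summary of the significant rho.

BIC differences are reported as Bayes factors on the doubled scale
(BF = 2 * dBIC), read against the conventional bands: 0-2 weak, 2-6
positive, 6-10 strong support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import netautoreg
from .netautoreg import DisturbanceModel, FitResult
from .weights import InputError, WeightMatrix

logger = logging.getLogger(__name__)

BIC_TIE_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """A subset of weight-matrix labels; the empty subset is the null model."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def name(self) -> str:
        return ", ".join(self.labels) if self.labels else "null"

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RankedModel:
    spec: ModelSpec
    fit: FitResult

    @property
    def bic(self) -> float:
        return self.fit.bic


@dataclass
class BinResult:
    """Ranked model list for one time bin."""

    bin_label: str
    bin_index: int
    ranked: list[RankedModel]
    n: int

    @property
    def preferred(self) -> RankedModel:
        return self.ranked[0]

    @property
    def second(self) -> RankedModel:
        return self.ranked[1]

    def gap(self, to_rank: int) -> float:
        """BIC gap from the preferred model to the model at rank ``to_rank``."""
        return self.ranked[to_rank].bic - self.ranked[0].bic


@dataclass
class SelectionTable:
    """Per-bin rankings plus the aggregate frequency machinery."""

    bins: list[BinResult]
    matrix_labels: tuple[str, ...]

    def median_gaps(self) -> tuple[float, float]:
        return median_bic_gaps(self)

    def frequencies(self) -> pd.DataFrame:
        return inclusion_frequencies(self, self.matrix_labels)["per_matrix"]


@dataclass
class SignificanceCensus:
    """Single-matrix fits across bins: which were significant, and their rho."""

    matrix_label: str
    alpha: float
    n_significant: int
    n_tested: int
    significant_rhos: list[float]
    significant_bins: list[str]


def enumerate_models(matrix_labels: Sequence[str]) -> list[ModelSpec]:
    """All 2^k subsets of the candidate matrices, null first, size then
    lexicographic order — deterministic across runs."""
    labels = list(matrix_labels)
    if not 1 <= len(labels) <= 4:
        raise InputError("expected 1-4 candidate matrices")
    specs: list[ModelSpec] = []
    for size in range(len(labels) + 1):
        combos = sorted(
            [tuple(sorted(c)) for c in _combinations(labels, size)]
        )
        specs.extend(ModelSpec(c) for c in combos)
    return specs


def _combinations(items: Sequence[str], size: int):
    from itertools import combinations
    return combinations(items, size)


def sweep_bin(y: np.ndarray, matrices: Mapping[str, WeightMatrix],
              bin_label: str = "", bin_index: int = 0) -> BinResult:
    """Fit every matrix subset to one bin's outcome and rank by BIC.

    Ties within ``BIC_TIE_TOL`` are broken by parsimony (fewer matrices) then
    label order; non-converged fits sort last and stay flagged.
    """
    specs = enumerate_models(list(matrices))
    ranked: list[RankedModel] = []
    for spec in specs:
        w_list = tuple(matrices[lab] for lab in spec.labels)
        model = DisturbanceModel.intercept_only(y, w_list=w_list)
        res = netautoreg.fit(model)
        ranked.append(RankedModel(spec=spec, fit=res))

    def sort_key(rm: RankedModel):
        bad = not rm.fit.converged or not np.isfinite(rm.bic)
        bic_val = np.inf if bad else round(rm.bic / BIC_TIE_TOL) * BIC_TIE_TOL
        return (bad, bic_val, len(rm.spec), rm.spec.labels)

    ranked.sort(key=sort_key)
    return BinResult(bin_label=bin_label, bin_index=bin_index, ranked=ranked, n=y.size)


def bayes_factor(delta_bic: float) -> float:
    """Bayes factor on the doubled-difference scale: BF = 2 * dBIC.

    Interpretation bands (2 ln BF scale): 0-2 weak, 2-6 positive, 6-10 strong.
    """
    if delta_bic < 0:
        raise InputError("BIC difference must be nonnegative")
    return 2.0 * delta_bic


def bayes_factor_band(bf: float) -> str:
    if bf < 2:
        return "weak"
    if bf < 6:
        return "positive"
    if bf < 10:
        return "strong"
    return "very strong"


def inclusion_frequencies(table: SelectionTable,
                          matrix_labels: Sequence[str] | None = None) -> dict[str, pd.DataFrame]:
    """Per-matrix and per-spec inclusion counts over the top two models.

    A matrix present in both the preferred and the second-best model of one
    bin counts twice toward "overall", so each matrix's maximum is
    2 x #bins. Returns ``{"per_matrix": ..., "per_spec": ...}`` DataFrames in
    the selection-table layout (spec rows x preferred/2nd-best columns).
    """
    if not table.bins:
        raise InputError("no bins in selection table")
    labels = list(matrix_labels or table.matrix_labels)
    per_matrix = pd.DataFrame(0, index=labels, columns=["preferred", "second", "overall"])
    spec_names = [s.name for s in enumerate_models(labels)]
    per_spec = pd.DataFrame(0, index=spec_names, columns=["preferred", "second"])
    for b in table.bins:
        for rank, col in ((0, "preferred"), (1, "second")):
            spec = b.ranked[rank].spec
            per_spec.loc[spec.name, col] += 1
            for lab in spec.labels:
                per_matrix.loc[lab, col] += 1
    per_matrix["overall"] = per_matrix["preferred"] + per_matrix["second"]
    return {"per_matrix": per_matrix, "per_spec": per_spec}


def median_bic_gaps(table: SelectionTable) -> tuple[float, float]:
    """Medians across bins of the BIC gaps preferred->2nd and preferred->3rd."""
    usable = [b for b in table.bins if len(b.ranked) >= 3]
    if not usable:
        raise InputError("need at least one bin with >= 3 ranked models")
    g12 = float(np.median([b.gap(1) for b in usable]))
    g13 = float(np.median([b.gap(2) for b in usable]))
    return g12, g13


def significance_census(bin_vectors: Sequence[tuple[str, np.ndarray, WeightMatrix]],
                        alpha: float = 0.05) -> SignificanceCensus:
    """Single-matrix fits per bin; collect the bins with rho p < alpha.

    ``bin_vectors`` supplies (bin label, aligned outcome, aligned matrix)
    triples; bins whose fit fails or does not converge are excluded from the
    denominator and logged.
    """
    label = bin_vectors[0][2].label if bin_vectors else ""
    sig_rhos: list[float] = []
    sig_bins: list[str] = []
    tested = 0
    for bin_label, y, w in bin_vectors:
        try:
            res = netautoreg.fit(DisturbanceModel.intercept_only(y, w_list=(w,)))
        except Exception as exc:  # degenerate bin
            logger.warning("census: bin %s not estimable (%s)", bin_label, exc)
            continue
        if not res.converged or not np.isfinite(res.rho_p[0]):
            logger.warning("census: bin %s fit did not converge", bin_label)
            continue
        tested += 1
        if res.rho_p[0] < alpha:
            sig_rhos.append(float(res.rho[0]))
            sig_bins.append(bin_label)
    return SignificanceCensus(
        matrix_label=label, alpha=alpha,
        n_significant=len(sig_rhos), n_tested=tested,
        significant_rhos=sig_rhos, significant_bins=sig_bins,
    )


@dataclass
class RhoSummary:
    mean: float
    ci_low: float
    ci_high: float
    t_pvalue: float
    df: int
    flagged: bool = False
    note: str = ""


def summarize_significant_rhos(census: SignificanceCensus) -> RhoSummary:
    """One-sample t-test of the significant rho against zero; df = count - 1."""
    vals = np.asarray(census.significant_rhos, dtype=float)
    k = vals.size
    if k < 2:
        return RhoSummary(
            mean=float(vals.mean()) if k == 1 else np.nan,
            ci_low=np.nan, ci_high=np.nan, t_pvalue=np.nan,
            df=k - 1, flagged=True, note="fewer than 2 significant values",
        )
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    df = k - 1
    if sd == 0:
        return RhoSummary(mean=mean, ci_low=mean, ci_high=mean, t_pvalue=0.0 if mean else 1.0,
                          df=df, flagged=True, note="zero-width CI (all values equal)")
    t_res = stats.ttest_1samp(vals, 0.0)
    half = stats.t.ppf(0.975, df) * sd / np.sqrt(k)
    return RhoSummary(mean=mean, ci_low=mean - half, ci_high=mean + half,
                      t_pvalue=float(t_res.pvalue), df=df)


def even_odd_robustness(table: SelectionTable, matrix_label: str) -> dict[str, float]:
    """Fraction of a matrix's top-two inclusions that fall on even-indexed bins.

    A robustness probe against temporal clustering: if a result holds across
    the sampled period it should split roughly evenly between the two
    interleaved subsets of non-adjacent bins.
    """
    even = odd = 0
    for b in table.bins:
        included = any(
            matrix_label in b.ranked[r].spec.labels for r in (0, 1)
        )
        if included:
            if b.bin_index % 2 == 0:
                even += 1
            else:
                odd += 1
    total = even + odd
    if total == 0:
        return {"even_fraction": np.nan, "odd_fraction": np.nan, "n_inclusions": 0}
    return {
        "even_fraction": even / total,
        "odd_fraction": odd / total,
        "n_inclusions": total,
    }
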