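"""Per-lineage gene-expression / drug-response association engine.

For every (gene, drug, lineage) triple with enough cell lines, the
engine correlates the gene's expression with the drug's IC50/EC50 by
Spearman rank correlation over the pairwise-complete cell lines of that
lineage, then filters at p < alpha (strict, default 0.05).

Direction semantics follow the higher-IC50-equals-more-resistant
convention: a positive correlation means high expression accompanies a
high IC50 (the drug is *less* effective -> "resistance"); a negative
correlation means the drug works better when expression is higher
("sensitizing").
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .panel_io import HarmonizedPanel, VALID_METRICS
from .rank_stats import DEFAULT_EXACT_THRESHOLD, spearman_test

__all__ = [
    "PAN_LINEAGE",
    "AssociationConfig",
    "AssociationRecord",
    "SkippedTest",
    "AssociationMatrix",
    "RunSummary",
    "associate",
    "associate_all",
    "filter_significant",
    "adjust_pvalues",
    "build_matrix",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

#: Reserved lineage label for the pooled (all-lineage) analysis.
PAN_LINEAGE = "PAN"

Direction = Literal["resistance", "sensitizing"]


@dataclass(frozen=True)
class AssociationConfig:
    """Knobs of the association run.

    min_n is 5 because with fewer than 5 cell lines even a perfectly
    monotone pair cannot reach p < 0.05 two-sided under exact permutation
    enumeration (minimum two-sided p at n=4 is 2/24).
    """

    alpha: float = 0.05
    min_n: int = 5
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD
    metric_preference: tuple[str, ...] = ("EC50", "IC50")
    adjust_method: Literal["none", "benjamini_hochberg"] = "none"
    adjust_stratum: Literal["global", "per_drug", "per_lineage"] = "per_drug"
    include_pan: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_n < 3:
            raise ValueError("min_n must be at least 3")
        bad = set(self.metric_preference) - set(VALID_METRICS)
        if bad:
            raise ValueError(f"unknown metrics in preference order: {sorted(bad)}")


@dataclass(frozen=True)
class AssociationRecord:
    """One tested (gene, drug, lineage) triple."""

    gene_id: str
    drug_id: str
    lineage: str
    metric: str
    n: int
    rho: float
    p_value: float
    method: str
    dataset_tag: str
    q_value: float | None = None

    @property
    def direction(self) -> Direction:
        return "resistance" if self.rho > 0 else "sensitizing"


@dataclass(frozen=True)
class SkippedTest:
    """A triple that could not be tested, with the reason."""

    gene_id: str
    drug_id: str
    lineage: str
    reason: Literal["insufficient_n", "degenerate", "no_response"]


@dataclass
class RunSummary:
    """Counts describing one associate_all run."""

    n_tested: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_skipped": self.n_skipped,
            "skip_reasons": dict(self.skip_reasons),
        }


def _response_series(
    panel: HarmonizedPanel, drug: str, config: AssociationConfig
) -> tuple[pd.Series, str] | None:
    """Response values for one drug keyed by cell line, honoring metric preference."""
    sub = panel.response.data[panel.response.data["drug"] == drug]
    if sub.empty:
        return None
    for metric in config.metric_preference:
        hit = sub[sub["metric"] == metric]
        if not hit.empty:
            return hit.set_index("cell_line")["value"], metric
    return None


def _associate_core(
    panel: HarmonizedPanel,
    gene: str,
    drug: str,
    lineage: str,
    config: AssociationConfig,
    expr_row: np.ndarray,
    resp_row: np.ndarray,
    metric: str,
) -> AssociationRecord | SkippedTest:
    ok = np.isfinite(expr_row) & np.isfinite(resp_row)
    if int(ok.sum()) < config.min_n:
        return SkippedTest(gene, drug, lineage, "insufficient_n")
    result = spearman_test(expr_row[ok], resp_row[ok], config.exact_threshold)
    if result.degenerate:
        return SkippedTest(gene, drug, lineage, "degenerate")
    return AssociationRecord(
        gene_id=gene,
        drug_id=drug,
        lineage=lineage,
        metric=metric,
        n=result.n,
        rho=result.rho,
        p_value=result.p_value,
        method=result.method,
        dataset_tag=panel.tag,
    )


def associate(
    panel: HarmonizedPanel,
    gene: str,
    drug: str,
    lineage: str,
    config: AssociationConfig | None = None,
) -> AssociationRecord | SkippedTest:
    """Correlate one gene's expression with one drug's response in one lineage.

    ``lineage`` may be the reserved ``PAN`` label for the pooled analysis.
    Pairs with a missing expression or response value are dropped
    (pairwise-complete); triples with fewer than ``min_n`` complete pairs
    or a constant variable are returned as :class:`SkippedTest`.
    """
    config = config or AssociationConfig()
    if gene not in panel.expression.data.index:
        raise KeyError(f"gene {gene!r} not in panel {panel.tag!r}")
    resp = _response_series(panel, drug, config)
    if resp is None:
        raise KeyError(f"drug {drug!r} not in panel {panel.tag!r}")
    values, metric = resp
    lines = panel.cell_lines if lineage == PAN_LINEAGE else panel.lines_in_lineage(lineage)
    expr_row = panel.expression.data.loc[gene, lines].to_numpy(dtype=float)
    resp_row = values.reindex(lines).to_numpy(dtype=float)
    return _associate_core(panel, gene, drug, lineage, config, expr_row, resp_row, metric)


def associate_all(
    panel: HarmonizedPanel,
    genes: Sequence[str] | None = None,
    drugs: Sequence[str] | None = None,
    config: AssociationConfig | None = None,
) -> tuple[list[AssociationRecord], RunSummary]:
    """Run every (gene, drug, lineage) test; deterministic lexicographic order.

    PAN (pooled) rows are appended per lineage block only when the config
    enables them.  Returns the records plus a summary of skip reasons.
    """
    config = config or AssociationConfig()
    gene_list = sorted(genes) if genes is not None else sorted(panel.expression.gene_ids)
    drug_list = sorted(drugs) if drugs is not None else panel.response.drug_ids
    lineage_list = sorted(panel.lineages)
    if config.include_pan:
        lineage_list = lineage_list + [PAN_LINEAGE]
    all_lines = panel.cell_lines
    line_pos = {c: i for i, c in enumerate(all_lines)}
    lines_of = {
        lineage: np.array(
            [line_pos[c] for c in (all_lines if lineage == PAN_LINEAGE
                                   else panel.lines_in_lineage(lineage))],
            dtype=int,
        )
        for lineage in lineage_list
    }
    resp_of: dict[str, tuple[np.ndarray, str]] = {}
    for drug in drug_list:
        resp = _response_series(panel, drug, config)
        if resp is None:
            raise KeyError(f"drug {drug!r} not in panel {panel.tag!r}")
        values, metric = resp
        resp_of[drug] = (values.reindex(all_lines).to_numpy(dtype=float), metric)

    records: list[AssociationRecord] = []
    summary = RunSummary()
    for gene in gene_list:
        if gene not in panel.expression.data.index:
            raise KeyError(f"gene {gene!r} not in panel {panel.tag!r}")
        expr_full = panel.expression.data.loc[gene, all_lines].to_numpy(dtype=float)
        for drug in drug_list:
            resp_full, metric = resp_of[drug]
            for lineage in lineage_list:
                idx = lines_of[lineage]
                out = _associate_core(
                    panel, gene, drug, lineage, config,
                    expr_full[idx], resp_full[idx], metric,
                )
                if isinstance(out, SkippedTest):
                    summary.n_skipped += 1
                    summary.skip_reasons[out.reason] += 1
                else:
                    summary.n_tested += 1
                    records.append(out)
    logger.info(
        "panel %s: %d test(s), %d skipped %s",
        panel.tag,
        summary.n_tested,
        summary.n_skipped,
        dict(summary.skip_reasons),
    )
    return records, summary


def filter_significant(
    records: Iterable[AssociationRecord], alpha: float = 0.05
) -> list[AssociationRecord]:
    """Keep records with p strictly below alpha (q when adjustment was applied)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    kept = []
    for r in records:
        p = r.q_value if r.q_value is not None else r.p_value
        if p < alpha:
            kept.append(r)
    return kept


def adjust_pvalues(
    records: Sequence[AssociationRecord],
    method: Literal["none", "benjamini_hochberg"] = "none",
    stratum: Literal["global", "per_drug", "per_lineage"] = "per_drug",
) -> list[AssociationRecord]:
    """Attach q-values; Benjamini-Hochberg step-up within each stratum.

    ``method="none"`` copies p to q (the default pipeline uses raw p,
    matching the strict p < 0.05 filter).
    """
    if method not in ("none", "benjamini_hochberg"):
        raise ValueError(f"unknown adjustment method {method!r}")
    records = list(records)
    if method == "none":
        return [replace(r, q_value=r.p_value) for r in records]
    if not records:
        return []

    def key(r: AssociationRecord) -> str:
        if stratum == "global":
            return ""
        if stratum == "per_drug":
            return r.drug_id
        if stratum == "per_lineage":
            return r.lineage
        raise ValueError(f"unknown stratum {stratum!r}")

    out: list[AssociationRecord | None] = [None] * len(records)
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(key(r), []).append(i)
    for idx in groups.values():
        pvals = [records[i].p_value for i in idx]
        q = multipletests(pvals, method="fdr_bh")[1]
        for i, qv in zip(idx, q):
            out[i] = replace(records[i], q_value=float(qv))
    return out  # type: ignore[return-value]


@dataclass
class AssociationMatrix:
    """Lineage x drug matrix of one gene's associations with a significance mask.

    ``rho``/``p``/``n`` hold every tested cell; ``mask`` is True where the
    cell fails the significance filter, and masked cells export as NA.
    """

    gene_id: str
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    mask: pd.DataFrame
    alpha: float

    @property
    def lineages(self) -> list[str]:
        return list(self.rho.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.rho.columns)

    def signed_export(self) -> pd.DataFrame:
        """Rho with masked cells NA plus a parallel direction label frame."""
        return self.rho.where(~self.mask)

    def direction_export(self) -> pd.DataFrame:
        labels = self.rho.map(
            lambda v: "" if pd.isna(v) else ("resistance" if v > 0 else "sensitizing")
        )
        return labels.where(~self.mask, "")


def build_matrix(
    records: Sequence[AssociationRecord], gene: str, alpha: float = 0.05
) -> AssociationMatrix:
    """Assemble one gene's lineage x drug significance-masked matrix."""
    records = [r for r in records]
    bad = {r.gene_id for r in records} - {gene}
    if bad:
        raise ValueError(f"records for other gene(s) {sorted(bad)} mixed into matrix for {gene!r}")
    lineages = sorted({r.lineage for r in records})
    drugs = sorted({r.drug_id for r in records})
    shape = (len(lineages), len(drugs))
    rho = pd.DataFrame(np.full(shape, np.nan), index=lineages, columns=drugs)
    p = rho.copy()
    n = pd.DataFrame(np.zeros(shape, dtype=int), index=lineages, columns=drugs)
    for r in records:
        rho.loc[r.lineage, r.drug_id] = r.rho
        p.loc[r.lineage, r.drug_id] = r.p_value
        n.loc[r.lineage, r.drug_id] = r.n
    mask = p.isna() | (p >= alpha)
    return AssociationMatrix(gene, rho, p, n, mask, alpha)


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Flat table view of association records (stable column order)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "drug": r.drug_id,
                "lineage": r.lineage,
                "metric": r.metric,
                "n": r.n,
                "rho": r.rho,
                "p": r.p_value,
                "q": r.q_value if r.q_value is not None else math.nan,
                "direction": r.direction,
                "method": r.method,
                "dataset": r.dataset_tag,
            }
            for r in records
        ],
        columns=[
            "gene",
            "drug",
            "lineage",
            "metric",
            "n",
            "rho",
            "p",
            "q",
            "direction",
            "method",
            "dataset",
        ],
    )
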