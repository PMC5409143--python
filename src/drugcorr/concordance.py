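"""Cross-panel concordance of gene/drug/lineage associations.

An association found in one cell-line panel (e.g. CCLE-style) is
*confirmed* when the same (gene, drug, lineage) triple is significant at
the same alpha in an independent panel (e.g. GDSC-style) with the same
correlation sign.  Because the two panels may use different response
metrics (EC50 in one, IC50 in the other), the sign semantics still
agree: both are higher-equals-more-resistant, so no sign flip is needed.

Drug and lineage vocabularies differ across sources; optional injective
rename maps translate panel-A keys into panel-B vocabulary before the
join.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .association import AssociationRecord

__all__ = [
    "ConcordanceRecord",
    "ConcordanceStatus",
    "match_keys",
    "concordance_table",
    "count_confirmed_lineages",
    "status_counts",
    "concordance_to_frame",
]

ConcordanceStatus = Literal["confirmed", "discordant_sign", "only_a", "only_b", "absent"]

Key = tuple[str, str, str]  # (gene, drug, lineage) in panel-B vocabulary


@dataclass(frozen=True)
class ConcordanceRecord:
    """Cross-panel comparison of one (gene, drug, lineage) triple."""

    gene_id: str
    drug_id: str
    lineage: str
    rho_a: float | None
    p_a: float | None
    n_a: int | None
    metric_a: str | None
    rho_b: float | None
    p_b: float | None
    n_b: int | None
    metric_b: str | None
    status: ConcordanceStatus


def _check_injective(name: str, mapping: Mapping[str, str] | None) -> None:
    if mapping is None:
        return
    values = list(mapping.values())
    if len(set(values)) != len(values):
        raise ValueError(f"{name} map is not injective")


def _mapped_key(
    r: AssociationRecord,
    drug_map: Mapping[str, str] | None,
    lineage_map: Mapping[str, str] | None,
) -> Key:
    drug = drug_map.get(r.drug_id, r.drug_id) if drug_map else r.drug_id
    lineage = lineage_map.get(r.lineage, r.lineage) if lineage_map else r.lineage
    return (r.gene_id, drug, lineage)


def match_keys(
    records_a: Sequence[AssociationRecord],
    records_b: Sequence[AssociationRecord],
    drug_map: Mapping[str, str] | None = None,
    lineage_map: Mapping[str, str] | None = None,
) -> tuple[
    dict[Key, tuple[AssociationRecord | None, AssociationRecord | None]],
    list[Key],
    list[Key],
]:
    """Join the two record sets on (gene, mapped drug, mapped lineage).

    Returns the keyed pair table plus the keys present only in A and only
    in B.  Maps translate panel-A names into panel-B vocabulary and must
    be injective.
    """
    _check_injective("drug", drug_map)
    _check_injective("lineage", lineage_map)
    pairs: dict[Key, tuple[AssociationRecord | None, AssociationRecord | None]] = {}
    for r in records_a:
        pairs[_mapped_key(r, drug_map, lineage_map)] = (r, None)
    for r in records_b:
        key = (r.gene_id, r.drug_id, r.lineage)
        a, _ = pairs.get(key, (None, None))
        pairs[key] = (a, r)
    only_a = sorted(k for k, (a, b) in pairs.items() if b is None)
    only_b = sorted(k for k, (a, b) in pairs.items() if a is None)
    return pairs, only_a, only_b


def _status(
    a: AssociationRecord | None, b: AssociationRecord | None, alpha: float
) -> ConcordanceStatus:
    sig_a = a is not None and a.p_value < alpha
    sig_b = b is not None and b.p_value < alpha
    if sig_a and sig_b:
        same_sign = (a.rho > 0) == (b.rho > 0) and a.rho != 0 and b.rho != 0
        return "confirmed" if same_sign else "discordant_sign"
    if sig_a:
        return "only_a"
    if sig_b:
        return "only_b"
    return "absent"


def concordance_table(
    records_a: Sequence[AssociationRecord],
    records_b: Sequence[AssociationRecord],
    alpha: float = 0.05,
    drug_map: Mapping[str, str] | None = None,
    lineage_map: Mapping[str, str] | None = None,
) -> list[ConcordanceRecord]:
    """One ConcordanceRecord per joined triple, in deterministic key order.

    The significance filter (p < alpha, strict) is applied here on raw
    p-values from both panels; records may be passed unfiltered.
    """
    pairs, _, _ = match_keys(records_a, records_b, drug_map, lineage_map)
    out: list[ConcordanceRecord] = []
    for key in sorted(pairs):
        a, b = pairs[key]
        gene, drug, lineage = key
        out.append(
            ConcordanceRecord(
                gene_id=gene,
                drug_id=drug,
                lineage=lineage,
                rho_a=a.rho if a else None,
                p_a=a.p_value if a else None,
                n_a=a.n if a else None,
                metric_a=a.metric if a else None,
                rho_b=b.rho if b else None,
                p_b=b.p_value if b else None,
                n_b=b.n if b else None,
                metric_b=b.metric if b else None,
                status=_status(a, b, alpha),
            )
        )
    return out


def count_confirmed_lineages(
    table: Iterable[ConcordanceRecord],
    gene: str,
    drug: str,
    required_sign: Literal["positive", "negative", "any"] = "any",
) -> int:
    """Distinct lineages where (gene, drug) is confirmed with the required sign."""
    lineages = set()
    for r in table:
        if r.status != "confirmed" or r.gene_id != gene or r.drug_id != drug:
            continue
        if required_sign == "positive" and not (r.rho_a > 0):
            continue
        if required_sign == "negative" and not (r.rho_a < 0):
            continue
        lineages.add(r.lineage)
    return len(lineages)


def status_counts(table: Iterable[ConcordanceRecord]) -> dict[str, int]:
    counts = {s: 0 for s in ("confirmed", "discordant_sign", "only_a", "only_b", "absent")}
    for r in table:
        counts[r.status] += 1
    return counts


def concordance_to_frame(table: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """Flat table view with both panels' statistics and the status column."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "drug": r.drug_id,
                "lineage": r.lineage,
                "rho_a": r.rho_a,
                "p_a": r.p_a,
                "n_a": r.n_a,
                "metric_a": r.metric_a,
                "rho_b": r.rho_b,
                "p_b": r.p_b,
                "n_b": r.n_b,
                "metric_b": r.metric_b,
                "status": r.status,
            }
            for r in table
        ],
        columns=[
            "gene", "drug", "lineage",
            "rho_a", "p_a", "n_a", "metric_a",
            "rho_b", "p_b", "n_b", "metric_b",
            "status",
        ],
    )
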