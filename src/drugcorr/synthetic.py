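"""Synthetic cell-line panels with known ground truth.

Emulates the three input tables of a CCLE/GDSC-style panel — expression
matrix, drug-response table, lineage annotation — with *planted*
gene-drug Spearman effects, so the whole pipeline is testable without
any external download.

Effects are planted through a Gaussian copula: within a lineage, the
latent (expression, log-response) pair of a planted triple is bivariate
normal with Pearson correlation r = 2*sin(pi*rho_s/6), the closed-form
latent correlation whose population Spearman equals the requested
rho_s.  Responses are exponentiated to positive, right-skewed IC50-like
values; since Spearman is invariant under strictly monotone maps, the
exponentiation changes no rank statistic (and the tests check that).

Ties are injected by rounding a chosen fraction of expression values to
one decimal; missingness by dropping a fraction of response records.
Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    ExpressionMatrix,
    LineageAnnotation,
    ResponseTable,
)

__all__ = ["PlantedEffect", "PanelSpec", "pearson_for_target_spearman", "generate",
           "ground_truth_frame"]

#: Log-scale spread of the synthetic IC50-like responses (dex units).
_LOG_RESPONSE_SD = 1.5


@dataclass(frozen=True)
class PlantedEffect:
    """One (gene, drug, lineage) triple with a target population Spearman."""

    gene: str
    drug: str
    lineage: str
    rho_s: float


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for one synthetic panel.

    Gene identifiers are G0001..G{n_genes}; lineages are (label, size)
    pairs.  At most one effect may be planted per (drug, lineage) so each
    planted Spearman target is exact rather than entangled with another.
    """

    n_genes: int
    drugs: tuple[str, ...]
    lineages: tuple[tuple[str, int], ...]
    planted_effects: tuple[PlantedEffect, ...] = ()
    tie_rate: float = 0.0
    missing_rate: float = 0.0
    metric: str = "IC50"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or not self.drugs or not self.lineages:
            raise ValueError("spec needs >=1 gene, >=1 drug and >=1 lineage")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("drug names must be unique")
        labels = [lab for lab, _ in self.lineages]
        if len(set(labels)) != len(labels):
            raise ValueError("lineage labels must be unique")
        for rate, name in ((self.tie_rate, "tie_rate"), (self.missing_rate, "missing_rate")):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        genes = set(self.gene_ids)
        seen: set[tuple[str, str]] = set()
        for e in self.planted_effects:
            if e.gene not in genes:
                raise ValueError(f"planted effect references unknown gene {e.gene!r}")
            if e.drug not in self.drugs:
                raise ValueError(f"planted effect references unknown drug {e.drug!r}")
            if e.lineage not in labels:
                raise ValueError(f"planted effect references unknown lineage {e.lineage!r}")
            if not -1.0 < e.rho_s < 1.0:
                raise ValueError("target Spearman must lie in (-1, 1)")
            key = (e.drug, e.lineage)
            if key in seen:
                raise ValueError(f"multiple effects planted for drug/lineage {key}")
            seen.add(key)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def pearson_for_target_spearman(rho_s: float) -> float:
    """Latent bivariate-normal Pearson r whose population Spearman is rho_s.

    Closed form r = 2*sin(pi*rho_s/6); the endpoints +-1 map to +-1.
    """
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError("target Spearman must lie in [-1, 1]")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate(
    spec: PanelSpec,
) -> tuple[ExpressionMatrix, ResponseTable, LineageAnnotation]:
    """Draw one panel from the spec; fully deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted = {(e.drug, e.lineage): e for e in spec.planted_effects}

    expr_cols: dict[str, np.ndarray] = {}
    lineage_of: dict[str, str] = {}
    resp_rows: list[tuple[str, str, str, float]] = []
    counter = 0
    for lineage, n_lines in spec.lineages:
        # latent standard-normal expression, one row per gene
        z_expr = rng.standard_normal((spec.n_genes, n_lines))
        names = []
        for _ in range(n_lines):
            counter += 1
            names.append(f"CL{counter:04d}")
        for j, name in enumerate(names):
            expr_cols[name] = z_expr[:, j]
            lineage_of[name] = lineage
        for drug in spec.drugs:
            effect = planted.get((drug, lineage))
            eps = rng.standard_normal(n_lines)
            if effect is None:
                z_resp = eps
            else:
                r = pearson_for_target_spearman(effect.rho_s)
                z_resp = r * z_expr[gene_pos[effect.gene]] + math.sqrt(1.0 - r * r) * eps
            values = np.exp(_LOG_RESPONSE_SD * z_resp)
            for name, v in zip(names, values):
                resp_rows.append((name, drug, spec.metric, float(v)))

    expr = pd.DataFrame(expr_cols, index=pd.Index(genes, name="gene"))
    expr = expr + 5.0  # shift to a plausible log2-expression scale
    if spec.tie_rate > 0.0:
        mask = rng.random(expr.shape) < spec.tie_rate
        rounded = expr.round(1)
        expr = expr.where(~mask, rounded)

    resp = pd.DataFrame(resp_rows, columns=["cell_line", "drug", "metric", "value"])
    resp["units"] = "uM"
    if spec.missing_rate > 0.0:
        keep = rng.random(len(resp)) >= spec.missing_rate
        resp = resp[keep].reset_index(drop=True)

    return (
        ExpressionMatrix(expr),
        ResponseTable(resp),
        LineageAnnotation(lineage_of),
    )


def ground_truth_frame(spec: PanelSpec) -> pd.DataFrame:
    """Planted triples as a flat table (for the simulate command's output)."""
    return pd.DataFrame(
        [
            {"gene": e.gene, "drug": e.drug, "lineage": e.lineage, "target_spearman": e.rho_s}
            for e in spec.planted_effects
        ],
        columns=["gene", "drug", "lineage", "target_spearman"],
    )
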