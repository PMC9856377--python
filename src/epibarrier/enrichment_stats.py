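"""Upstream-regulator statistics over a differential-expression table.

Given a DESeq2-style results table (gene, log2 fold change, p, adjusted p)
and a signed regulator -> target network, each regulator is scored by

* an overlap p-value: one-sided hypergeometric tail (Fisher's exact test)
  for the overlap between the regulator's targets and the selected
  differentially-expressed (DE) gene set, and
* an activation z-score: with unit edge weights,
  ``z = (n_agree - n_disagree) / sqrt(n_agree + n_disagree)`` over the
  DE-overlapping targets, where "agree" means the observed fold-change sign
  matches the sign expected under regulator activation. Positive z predicts
  an activated regulator, negative an inhibited one.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedResultError, ValidationError

__all__ = [
    "RegulatorNetwork",
    "RegulatorResult",
    "select_de_genes",
    "overlap_pvalue",
    "overlap_pvalue_exact",
    "activation_zscore",
    "rank_regulators",
    "read_network_tsv",
    "write_network_tsv",
]

_DE_COLUMNS = ("gene", "log2fc", "pvalue", "padj")


@dataclass(frozen=True)
class RegulatorNetwork:
    """Signed regulator -> target map: ``{regulator: {gene: +1 or -1}}``."""

    edges: dict[str, dict[str, int]]

    def __post_init__(self):
        for reg, targets in self.edges.items():
            if not targets:
                raise ValidationError(f"regulator {reg!r} has no targets")
            if any(s not in (-1, 1) for s in targets.values()):
                raise ValidationError(f"regulator {reg!r} has invalid signs")

    @property
    def regulators(self) -> list[str]:
        return list(self.edges)

    def targets(self, regulator: str) -> dict[str, int]:
        try:
            return self.edges[regulator]
        except KeyError:
            raise ValidationError(f"unknown regulator {regulator!r}") from None


def _validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"DE table lacks columns {missing}")
    if len(table) == 0:
        raise ValidationError("DE table is empty")
    if table["gene"].duplicated().any():
        raise ValidationError("DE table has duplicate gene ids")
    for col in ("pvalue", "padj"):
        p = table[col].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError(f"{col} outside [0, 1]")
    return table


def select_de_genes(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = True,
) -> dict[str, int]:
    """Signed DE gene set: ``{gene: sign(log2fc)}`` passing both thresholds."""
    table = _validate_de_table(table)
    if lfc_threshold < 0 or p_threshold < 0:
        raise ValidationError("thresholds must be >= 0")
    p = table["padj" if use_adjusted else "pvalue"].to_numpy(dtype=float)
    lfc = table["log2fc"].to_numpy(dtype=float)
    keep = (np.abs(lfc) >= lfc_threshold) & (p <= p_threshold)
    genes = table["gene"].to_numpy()[keep]
    signs = np.sign(lfc[keep]).astype(int)
    return {g: int(s) for g, s in zip(genes, signs) if s != 0}


def overlap_pvalue(de_set, targets, universe_size: int) -> float:
    """One-sided hypergeometric tail P(X >= overlap).

    ``X ~ Hypergeom(N=universe_size, K=|targets|, n=|de_set|)`` and the
    observed value is ``|de_set & targets|``.
    """
    de = set(de_set)
    tg = set(targets)
    k = len(de & tg)
    n_union = len(de | tg)
    if universe_size < n_union:
        raise ValidationError(
            f"universe ({universe_size}) smaller than |de_set U targets| ({n_union})"
        )
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(tg), len(de)))


def overlap_pvalue_exact(universe: int, n_targets: int, n_de: int, overlap: int) -> Fraction:
    """Exact-fraction enumeration of the hypergeometric tail (oracle path).

    Sums ``C(K, i) C(N-K, n-i) / C(N, n)`` for ``i >= overlap`` with integer
    combinatorics; independent of scipy.
    """
    if not (0 <= n_targets <= universe and 0 <= n_de <= universe):
        raise ValidationError("inconsistent counts")
    if overlap < 0 or overlap > min(n_targets, n_de):
        raise ValidationError("overlap outside feasible range")
    denom = comb(universe, n_de)
    num = sum(
        comb(n_targets, i) * comb(universe - n_targets, n_de - i)
        for i in range(overlap, min(n_targets, n_de) + 1)
    )
    return Fraction(num, denom)


def activation_zscore(de_set: dict[str, int], targets: dict[str, int]) -> float:
    """Unit-weight activation z-score over the DE-overlapping signed targets.

    Raises :class:`UndefinedResultError` when no target overlaps the DE set
    (no evidence either way — distinct from z = 0).
    """
    overlap = [g for g in targets if g in de_set]
    if not overlap:
        raise UndefinedResultError("no DE-overlapping targets; z-score undefined")
    agree = sum(1 for g in overlap if de_set[g] == targets[g])
    disagree = len(overlap) - agree
    return float((agree - disagree) / np.sqrt(agree + disagree))


@dataclass(frozen=True)
class RegulatorResult:
    """Scores of one upstream regulator."""

    regulator: str
    overlap_p: float
    z_score: float  # nan when undefined (no overlap)
    n_overlap: int
    n_targets: int
    target_directions: dict[str, str]  # gene -> 'agree' | 'disagree'


def rank_regulators(
    table: pd.DataFrame,
    network: RegulatorNetwork,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = True,
    universe_size: int | None = None,
) -> list[RegulatorResult]:
    """Score every regulator and sort by overlap p (ties: |z| desc, then id).

    The universe defaults to the number of genes in the DE results table.
    """
    de_set = select_de_genes(table, lfc_threshold, p_threshold, use_adjusted)
    if not de_set:
        raise ValidationError("DE selection is empty; nothing to rank")
    if universe_size is None:
        universe_size = len(table)
    results = []
    for reg in network.regulators:
        targets = network.targets(reg)
        p = overlap_pvalue(de_set, targets, universe_size)
        overlap = [g for g in targets if g in de_set]
        try:
            z = activation_zscore(de_set, targets)
        except UndefinedResultError:
            z = float("nan")
        directions = {
            g: ("agree" if de_set[g] == targets[g] else "disagree") for g in overlap
        }
        results.append(
            RegulatorResult(
                regulator=reg,
                overlap_p=p,
                z_score=z,
                n_overlap=len(overlap),
                n_targets=len(targets),
                target_directions=directions,
            )
        )
    results.sort(
        key=lambda r: (
            r.overlap_p,
            -(abs(r.z_score) if np.isfinite(r.z_score) else -1.0),
            r.regulator,
        )
    )
    return results


def read_network_tsv(path) -> RegulatorNetwork:
    """Read a GMT-like signed network: ``regulator<TAB>sign<TAB>target...`` per line."""
    edges: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed network line: {line!r}")
            reg, sign, targets = parts[0], int(parts[1]), parts[2:]
            edges.setdefault(reg, {})
            for g in targets:
                if g in edges[reg]:
                    raise ValidationError(f"duplicate target {g!r} for regulator {reg!r}")
                edges[reg][g] = sign
    return RegulatorNetwork(edges)


def write_network_tsv(network: RegulatorNetwork, path) -> None:
    """Write the network in the GMT-like signed TSV layout (one sign per line)."""
    with open(path, "w") as fh:
        for reg, targets in network.edges.items():
            for sign in (1, -1):
                genes = [g for g, s in targets.items() if s == sign]
                if genes:
                    fh.write("\t".join([reg, str(sign), *genes]) + "\n")
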