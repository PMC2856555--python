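"""Continuous-phenotype gene-set enrichment against the instability index.

Probes are ordered by their signed Pearson correlation with the per-sample
instability index, and each gene set is scored with the weighted
Kolmogorov–Smirnov-style running sum: walking down the ranking, the sum
rises by |r|^weight (normalized over the set's members) at each member probe
and falls by 1/(N − m) at each non-member; the enrichment score (ES) is the
extremum of the walk.  Significance comes from a phenotype-permutation null:
the per-tissue index values are shuffled across tissues (replicate arrays of
a tissue move as a block, respecting exchangeability), the full
ranking-and-scoring pipeline is re-run per permutation, and each set's
normalized enrichment score (NES) and nominal p-value are computed against
its own same-signed null scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "read_gmt",
    "read_annotation",
    "map_sets_to_probes",
    "correlation_ranking",
    "enrichment_score",
    "permutation_significance",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of probe or gene identifiers."""

    name: str
    members: frozenset[str]
    description: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: tab-separated ``name<TAB>description<TAB>member...``."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line needs name, description and ≥1 member: {line!r}")
        sets.append(GeneSet(name=fields[0], description=fields[1],
                            members=frozenset(m for m in fields[2:] if m)))
    return sets


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """Read a ``gene_symbol,probe_id`` CSV into a gene → probes mapping."""
    table = pd.read_csv(path, dtype=str)
    for col in ("gene_symbol", "probe_id"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    mapping: dict[str, list[str]] = {}
    for gene, probe in zip(table["gene_symbol"], table["probe_id"]):
        mapping.setdefault(gene, []).append(probe)
    return mapping


def map_sets_to_probes(
    sets: list[GeneSet], annotation: dict[str, list[str]]
) -> list[GeneSet]:
    """Expand gene-symbol sets to probe-level sets (a gene brings all its probes)."""
    out = []
    for s in sets:
        probes = frozenset(p for g in s.members for p in annotation.get(g, []))
        out.append(GeneSet(name=s.name, members=probes, description=s.description))
    return out


def correlation_ranking(expr: ExpressionMatrix) -> pd.Series:
    """Probes ordered by signed Pearson r with the phenotype, descending.

    Ties (including zero-variance probes, whose r is defined as 0) break
    deterministically by probe id.
    """
    if expr.phenotype is None:
        raise ValueError("ranking requires a phenotype")
    r = _correlations(_standardize_rows(expr.values.to_numpy(dtype=float)),
                      expr.phenotype.to_numpy())
    series = pd.Series(r, index=expr.probe_ids, name="r").sort_index()
    return series.sort_values(ascending=False, kind="mergesort")


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    norms[norms == 0] = 1.0  # zero-variance probes → r = 0
    return centered / norms


def _correlations(x_std: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    norm = np.sqrt((yc**2).sum())
    if norm == 0:
        raise ValueError("phenotype has zero variance")
    return x_std @ (yc / norm)


def enrichment_score(
    ranking: pd.Series, members, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score of ``members`` in ``ranking``.

    ``ranking`` is the descending correlation ranking; the returned running
    sum has N+1 points starting and ending at zero, and ES is its extremum
    (largest absolute deviation).  Member identifiers absent from the
    ranking are ignored.
    """
    members = frozenset(members) & set(ranking.index)
    n = len(ranking)
    m = len(members)
    if m == 0 or m == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranking universe")
    hit = ranking.index.isin(members)
    w = np.abs(ranking.to_numpy()) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # degenerate all-zero correlations: fall back to unweighted
        w_hit = hit.astype(float)
        total = float(m)
    steps = w_hit / total - (~hit) / (n - m)
    running = np.concatenate([[0.0], np.cumsum(steps)])
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _block_permutations(
    tissue_of: pd.Series, phenotype: pd.Series, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample phenotype under tissue-block permutation; row 0 is observed."""
    tissues = tissue_of.unique()
    tissue_pheno = np.array([phenotype[tissue_of == t].iloc[0] for t in tissues])
    tissue_idx = np.array([np.where(tissues == t)[0][0] for t in tissue_of])
    perms = np.empty((n_perm + 1, len(tissue_of)))
    perms[0] = tissue_pheno[tissue_idx]
    for i in range(1, n_perm + 1):
        shuffled = rng.permutation(tissue_pheno)
        perms[i] = shuffled[tissue_idx]
    return perms


def _es_from_positions(pos, w, n_universe):
    """Vectorized ES for one set across permutations, from hit positions.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately before or after a hit; this evaluates only those points.
    ``pos``/``w``: (n_perm, m) hit positions (0-based rank) and weights.
    """
    n_perm, m = pos.shape
    order = np.argsort(pos, axis=1)
    p = np.take_along_axis(pos, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    total = ws.sum(axis=1, keepdims=True)
    degenerate = total[:, 0] == 0
    if degenerate.any():
        ws[degenerate] = 1.0
        total = ws.sum(axis=1, keepdims=True)
    cum = np.cumsum(ws, axis=1)
    j = np.arange(1, m + 1)[None, :]
    miss_rate = 1.0 / (n_universe - m)
    misses = (p + 1 - j) * miss_rate  # misses preceding each hit
    after = cum / total - misses
    before = (cum - ws) / total - misses
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


def permutation_significance(
    expr: ExpressionMatrix,
    sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    chunk: int = 200,
) -> pd.DataFrame:
    """ES, NES and nominal p for every gene set under the permutation null.

    Returns a frame ``name,size,es,nes,p_nominal`` sorted by p.  Sets whose
    intersection with the expression universe falls outside
    [min_size, max_size] are skipped with a log entry.  NES divides each ES
    by the mean magnitude of same-signed null scores of the same set; the
    nominal p is the fraction of same-signed null scores at least as
    extreme, with a +1 pseudocount in numerator and denominator.
    """
    if expr.phenotype is None:
        raise ValueError("enrichment requires a phenotype")
    if n_perm < 50:
        logger.warning("n_perm=%d is small; permutation p-values will be unstable", n_perm)
    universe = expr.probe_ids.sort_values()
    values = expr.values.loc[universe].to_numpy(dtype=float)
    n_universe = len(universe)
    pos_of = {pid: i for i, pid in enumerate(universe)}

    kept, member_idx = [], []
    for s in sets:
        inter = frozenset(s.members) & set(universe)
        if not min_size <= len(inter) <= max_size:
            logger.info("skipping gene set %r: size %d outside [%d, %d]",
                        s.name, len(inter), min_size, max_size)
            continue
        kept.append(GeneSet(name=s.name, members=inter, description=s.description))
        member_idx.append(np.array(sorted(pos_of[p] for p in inter)))
    if not kept:
        return pd.DataFrame(columns=["name", "size", "es", "nes", "p_nominal"])

    rng = np.random.default_rng(seed)
    pheno = _block_permutations(expr.tissue_of, expr.phenotype, n_perm, rng)
    x_std = _standardize_rows(values)

    es_all = np.empty((len(kept), n_perm + 1))
    for start in range(0, n_perm + 1, chunk):
        block = pheno[start:start + chunk]
        yc = block - block.mean(axis=1, keepdims=True)
        yn = yc / np.sqrt((yc**2).sum(axis=1, keepdims=True))
        r = x_std @ yn.T  # probes × perms
        # descending r with deterministic id tie-break: universe is id-sorted
        # and mergesort is stable
        order = np.argsort(-r, axis=0, kind="stable")
        pos = np.empty_like(order)
        np.put_along_axis(pos, order, np.arange(n_universe)[:, None], axis=0)
        w_abs = np.abs(r) ** weight
        for si, idx in enumerate(member_idx):
            es_all[si, start:start + block.shape[0]] = _es_from_positions(
                pos[idx].T, w_abs[idx].T, n_universe
            )

    rows = []
    for si, s in enumerate(kept):
        es = es_all[si, 0]
        null = es_all[si, 1:]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        mean_mag = np.abs(same).mean() if len(same) else np.nan
        nes = es / mean_mag if mean_mag and not np.isnan(mean_mag) else np.nan
        p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + len(same))
        rows.append({"name": s.name, "size": s.size, "es": float(es),
                     "nes": float(nes), "p_nominal": float(p)})
    return pd.DataFrame(rows).sort_values(
        ["p_nominal", "name"], kind="mergesort"
    ).reset_index(drop=True)
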