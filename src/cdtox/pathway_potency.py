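"""Pathway-level potency aggregation and chemical screening.

Gene-level effective concentrations (EC_DEG) are aggregated into GO-term /
KEGG-pathway potencies (EC_GO, EC_KEGG) as geometric means over matched DEGs
(terms need at least three matched DEGs), fitted to log-normal potency
distributions on proportionally ranked ECs, clustered across samples, and
screened against chemical-gene/pathway association tables in the style of
the Comparative Toxicogenomics Database: a chemical passes when it affects
strictly more than a threshold fraction (default 50%) of a reference set of
co-detected DEGs or co-enriched terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "TermMap",
    "PathwayEC",
    "PotencyCurve",
    "read_gmt",
    "map_degs_to_terms",
    "ec_pathway",
    "potency_distribution",
    "cluster_terms",
    "screen_chemicals",
    "co_detected",
]


@dataclass(frozen=True)
class TermMap:
    """Flat gene-set annotation: term id -> member gene ids, per ontology."""

    ontology: str  # "GO" or "KEGG"
    terms: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for tid, members in self.terms.items():
            if not members:
                raise ValueError(f"term {tid} has an empty member set")


def read_gmt(path: str, ontology: str = "GO") -> TermMap:
    """Read a standard GMT file (term <tab> description <tab> genes...)."""
    terms: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = frozenset(g for g in parts[2:] if g)
    return TermMap(ontology, terms)


@dataclass(frozen=True)
class PathwayEC:
    """A responsive term with its matched DEGs and geometric-mean EC."""

    term: str
    ontology: str
    matched_degs: tuple
    ec: float


def map_degs_to_terms(
    deg_ecs: Mapping[str, float],
    term_map: TermMap,
    min_matched: int = 3,
) -> list[PathwayEC]:
    """Responsive terms: at least ``min_matched`` member genes are DEGs.

    ``deg_ecs`` maps DEG gene id -> EC_DEG.  Each responsive term gets the
    geometric mean of its matched DEG ECs.
    """
    out: list[PathwayEC] = []
    for tid in sorted(term_map.terms):
        matched = sorted(g for g in term_map.terms[tid] if g in deg_ecs)
        if len(matched) < min_matched:
            continue
        ec = ec_pathway([deg_ecs[g] for g in matched], min_values=min_matched)
        out.append(PathwayEC(tid, term_map.ontology, tuple(matched), ec))
    return out


def ec_pathway(matched_ecs: Sequence[float], min_values: int = 3) -> float:
    """Geometric mean of matched EC_DEG values (log-domain mean)."""
    ecs = np.asarray(matched_ecs, float)
    if len(ecs) < min_values:
        raise ValueError(f"need at least {min_values} EC values")
    if (ecs <= 0).any():
        raise ValueError("EC values must be positive")
    return float(np.exp(np.mean(np.log(ecs))))


@dataclass
class PotencyCurve:
    """Log-normal potency distribution over ECs at one biological level.

    mu/sigma are the maximum-likelihood mean and standard deviation of
    log10 EC; plotting positions are Hazen positions (i - 0.5)/n over the
    sorted ECs for the empirical cumulative curve.
    """

    level: str  # DEG | GO | KEGG
    mu: float
    sigma: float
    ecs: np.ndarray  # sorted
    degenerate: bool = False

    @property
    def plotting_positions(self) -> np.ndarray:
        n = len(self.ecs)
        return (np.arange(1, n + 1) - 0.5) / n

    def cdf(self, ec) -> np.ndarray:
        """Fitted log-normal CDF evaluated at concentration(s) ec."""
        x = np.log10(np.asarray(ec, float))
        if self.sigma == 0:
            return (x >= self.mu).astype(float)
        return stats.norm.cdf(x, loc=self.mu, scale=self.sigma)


def potency_distribution(ecs: Sequence[float], level: str = "DEG") -> PotencyCurve:
    """Fit a log-normal potency distribution to proportionally ranked ECs."""
    arr = np.sort(np.asarray(ecs, float))
    if len(arr) < 5:
        raise ValueError("at least 5 EC values required")
    if (arr <= 0).any():
        raise ValueError("EC values must be positive")
    logs = np.log10(arr)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs))  # MLE (ddof=0)
    return PotencyCurve(level, mu, sigma, arr, degenerate=(sigma == 0.0))


def cluster_terms(
    ec_profiles: pd.DataFrame,
    impute_factor: float = 10.0,
) -> dict:
    """Hierarchically cluster terms by their per-sample log10 EC profiles.

    ``ec_profiles``: term x sample EC matrix; missing ECs (term not
    responsive in a sample) are imputed as that sample's maximum EC times
    ``impute_factor`` and flagged.  Average linkage on Euclidean distance of
    log10 ECs; leaf order is deterministic (distance then id tie-break).

    Returns ``{"linkage", "leaves", "imputed", "newick"}``.
    """
    if ec_profiles.shape[0] < 1:
        raise ValueError("need at least one term")
    mat = ec_profiles.copy().astype(float)
    imputed = mat.isna()
    for col in mat.columns:
        if imputed[col].any():
            fill = mat[col].max(skipna=True) * impute_factor
            mat.loc[imputed[col], col] = fill
    logm = np.log10(mat.to_numpy())
    ids = list(ec_profiles.index.astype(str))
    if len(ids) == 1:
        return {"linkage": None, "leaves": ids, "imputed": imputed,
                "newick": f"{ids[0]};"}
    link = hierarchy.linkage(pdist(logm, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link)
    leaves = [ids[i] for i in order]
    newick = _to_newick(link, ids)
    return {"linkage": link, "leaves": leaves, "imputed": imputed, "newick": newick}


def _to_newick(link: np.ndarray, ids: list[str]) -> str:
    n = len(ids)
    nodes: dict[int, tuple[str, float]] = {i: (ids[i], 0.0) for i in range(n)}
    for i, (a, b, height, _) in enumerate(link):
        a, b = int(a), int(b)
        (na, ha), (nb, hb) = nodes[a], nodes[b]
        nodes[n + i] = (
            f"({na}:{max(height - ha, 0.0):.6g},{nb}:{max(height - hb, 0.0):.6g})",
            float(height),
        )
    return nodes[2 * n - 2][0] + ";"


def screen_chemicals(
    assoc: pd.DataFrame,
    reference_set: Iterable[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """CTD-style screen: chemicals affecting > threshold of the reference set.

    ``assoc`` has columns ``chemical_id`` and ``target_id``.  Coverage is
    |assoc(chemical) ∩ reference| / |reference|; the inequality is strict,
    so exactly 50% coverage fails the default screen.  Returns all chemicals
    sorted by coverage descending with a ``passes`` flag.
    """
    ref = set(reference_set)
    if not ref:
        raise ValueError("reference set must be non-empty")
    rows = []
    for chem, grp in assoc.groupby("chemical_id"):
        hit = set(grp["target_id"]) & ref
        cov = len(hit) / len(ref)
        rows.append({"chemical_id": chem, "coverage": cov,
                     "n_hits": len(hit), "passes": cov > threshold})
    out = pd.DataFrame(rows, columns=["chemical_id", "coverage", "n_hits", "passes"])
    return out.sort_values(["coverage", "chemical_id"],
                           ascending=[False, True]).reset_index(drop=True)


def co_detected(set_a: Iterable[str], set_b: Iterable[str]) -> set:
    """Genes (or terms) detected in both samples — the screen's reference set."""
    return set(set_a) & set(set_b)
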