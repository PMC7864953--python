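"""Photodegradation-product formation-kinetics network engine.

From a nontarget LC-MS peak table (per-sample areas over irradiation
timepoints plus a non-irradiated control) the engine

1. detects products whose peak area exceeds 3x the control,
2. Z-scores the formation kinetics of products detected at all timepoints,
3. builds a Pearson correlation network (two-tailed p below a threshold,
   positive correlations by default),
4. partitions it into Louvain communities, reporting those with >10 nodes,
5. correlates product and community kinetics with per-cell-line
   viability-inhibition vectors (log10, Z-scored) to flag
   cytotoxicity-associated products, and
6. exports Gephi-compatible GEXF/GraphML files.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeakTable",
    "KineticsMatrix",
    "ToxVector",
    "ProductNetwork",
    "detect_products",
    "build_kinetics",
    "pearson_r_p",
    "correlation_network",
    "louvain_communities",
    "toxicity_vectors",
    "associate_toxicity",
    "community_toxicity",
    "venn_summary",
    "export_network",
    "read_network",
    "zscore",
]

CELL_LINES = ("HEK-293", "HeLa", "HepG2")


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot Z-score a constant vector")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Peak table and detection
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """Long-format nontarget peak table.

    ``data`` columns: peak_id, mz, rt, sample, area.  ``timepoints`` maps
    each irradiated sample label to its irradiation duration in days;
    ``control`` names the non-irradiated control sample.
    """

    data: pd.DataFrame
    timepoints: Mapping[str, float]
    control: str = "control"

    def __post_init__(self) -> None:
        if (self.data["area"] < 0).any():
            raise ValueError("peak areas must be non-negative")
        if (self.data["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")

    @classmethod
    def from_csv(cls, path: str, control: str = "control") -> "PeakTable":
        df = pd.read_csv(path)
        tps = {}
        if "timepoint_days" in df.columns:
            irr = df[df["sample"] != control]
            tps = dict(irr.groupby("sample")["timepoint_days"].first())
        return cls(df, tps, control)

    def areas_wide(self) -> pd.DataFrame:
        """peak_id x sample area matrix (missing -> 0)."""
        return self.data.pivot_table(index="peak_id", columns="sample",
                                     values="area", fill_value=0.0, aggfunc="sum")

    def ordered_samples(self) -> list[str]:
        return [s for s, _ in sorted(self.timepoints.items(), key=lambda kv: kv[1])]

    def mz_of(self) -> pd.Series:
        return self.data.groupby("peak_id")["mz"].first()


def detect_products(
    peaks: PeakTable,
    ratio: float = 3.0,
) -> tuple[dict[str, set], set]:
    """Products detected per timepoint: area strictly above ratio x control.

    A zero control area is replaced by the table's noise floor (the minimum
    positive area in the table times 0.1); such products are flagged in the
    returned set of flagged ids.
    """
    wide = peaks.areas_wide()
    if peaks.control not in wide.columns:
        raise ValueError(f"control sample {peaks.control!r} absent from peak table")
    ctrl = wide[peaks.control].to_numpy(float)
    pos = wide.to_numpy(float)
    floor = 0.1 * pos[pos > 0].min() if (pos > 0).any() else 0.0
    flagged = set(wide.index[ctrl == 0])
    ctrl_eff = np.where(ctrl == 0, floor, ctrl)
    detected: dict[str, set] = {}
    for s in peaks.ordered_samples():
        mask = wide[s].to_numpy(float) > ratio * ctrl_eff
        detected[s] = set(wide.index[mask])
    return detected, flagged


@dataclass
class KineticsMatrix:
    """Z-scored formation kinetics: product x ordered timepoint matrix."""

    z: pd.DataFrame              # rows mean 0, sd 1
    areas: pd.DataFrame          # pre-normalization areas, same shape
    timepoints: np.ndarray       # days, ascending
    dropped_constant: list = field(default_factory=list)


def build_kinetics(
    peaks: PeakTable,
    detected: Optional[dict[str, set]] = None,
) -> KineticsMatrix:
    """Kinetics rows for products detected at every irradiated timepoint.

    Rows are Z-scored across timepoints; constant rows (sd 0) are dropped
    with their ids recorded.
    """
    samples = peaks.ordered_samples()
    if len(samples) < 3:
        raise ValueError("at least 3 irradiated timepoints are required")
    if detected is None:
        detected, _ = detect_products(peaks)
    keep = set.intersection(*(detected[s] for s in samples)) if samples else set()
    wide = peaks.areas_wide()
    keep_ids = sorted(keep & set(wide.index))
    if not keep_ids:
        raise ValueError("no products detected at all timepoints")
    areas = wide.loc[keep_ids, samples]
    vals = areas.to_numpy(float)
    sd = vals.std(axis=1)
    const = sd == 0
    dropped = [pid for pid, c in zip(keep_ids, const) if c]
    vals = vals[~const]
    ids = [pid for pid, c in zip(keep_ids, const) if not c]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    tps = np.array([peaks.timepoints[s] for s in samples], float)
    return KineticsMatrix(
        z=pd.DataFrame(z, index=ids, columns=samples),
        areas=areas.loc[ids],
        timepoints=tps,
        dropped_constant=dropped,
    )


# ---------------------------------------------------------------------------
# Correlation network and communities
# ---------------------------------------------------------------------------

def pearson_r_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-tailed p from the t distribution (df = n - 2)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(min(r, 1.0), -1.0)
    df = n - 2
    if df <= 0:
        return r, 1.0
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return r, 2.0 * float(stats.t.sf(abs(t), df))


@dataclass
class ProductNetwork:
    """Product correlation network with optional cell nodes and communities."""

    graph: nx.Graph
    communities: dict[str, int] = field(default_factory=dict)  # product -> label
    reported: list = field(default_factory=list)               # labels with >10 nodes

    @property
    def product_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("kind", "product") == "product"]


def correlation_network(
    kin: KineticsMatrix,
    p_threshold: float = 0.001,
    positive_only: bool = True,
) -> ProductNetwork:
    """All-pairs Pearson network over Z-scored kinetics rows.

    An edge joins two products when the two-tailed p of their correlation is
    below ``p_threshold`` (and r > 0 under the default similarity-network
    convention).  Edge weight is r.
    """
    ids = list(kin.z.index)
    mat = kin.z.to_numpy(float)
    n_t = mat.shape[1]
    g = nx.Graph()
    for pid in ids:
        g.add_node(pid, kind="product")
    # rows are Z-scored, so r is a dot product / n
    corr = (mat @ mat.T) / n_t
    df = n_t - 2
    for i, j in itertools.combinations(range(len(ids)), 2):
        r = float(np.clip(corr[i, j], -1.0, 1.0))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt(df / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), df))
        if p < p_threshold and (r > 0 or not positive_only):
            g.add_edge(ids[i], ids[j], weight=r, p=p)
    return ProductNetwork(g)


def louvain_communities(
    net: ProductNetwork,
    min_size: int = 11,
    seed: int = 0,
    resolution: float = 1.0,
) -> ProductNetwork:
    """Louvain partition of the product nodes, weighted by r.

    Communities with at least ``min_size`` nodes (i.e. >10 under the
    default) are "reported" and labeled 1..k by decreasing size; smaller
    groups keep a label but are not reported.  Deterministic for a fixed
    seed: nodes are canonicalized by sorting before the partition.
    """
    g = net.graph.subgraph(sorted(net.product_nodes)).copy()
    if g.number_of_edges() == 0:
        parts = [{n} for n in sorted(g.nodes)]
    else:
        parts = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed)
    parts = sorted(parts, key=lambda c: (-len(c), min(c)))
    communities: dict[str, int] = {}
    reported = []
    for label, members in enumerate(parts, start=1):
        if len(members) >= min_size:
            reported.append(label)
        for m in members:
            communities[m] = label
    net.communities = communities
    net.reported = reported
    for n, lab in communities.items():
        net.graph.nodes[n]["community"] = lab
    return net


# ---------------------------------------------------------------------------
# Toxicity association
# ---------------------------------------------------------------------------

@dataclass
class ToxVector:
    """Per-cell-line viability-inhibition kinetics over irradiation durations.

    ``inhibition`` holds the raw percent-inhibition values; ``z`` the
    log10-transformed, Z-scored vector used for correlation.
    """

    cell: str
    durations: np.ndarray
    inhibition: np.ndarray
    z: np.ndarray


def toxicity_vectors(
    viability: pd.DataFrame,
    concentration: Optional[float] = None,
    floor: float = 0.1,
) -> dict[str, ToxVector]:
    """Build per-cell toxicity vectors from a tidy viability table.

    ``viability`` columns: cell, duration_days, concentration, viability_pct.
    Inhibition = 100 - viability, floored at ``floor`` percent before log10,
    then Z-scored over durations.  By default the highest concentration
    present at every duration of a cell line is used.  Duration 0 (the
    non-irradiated control) is not a kinetics point and is excluded.
    """
    out: dict[str, ToxVector] = {}
    viability = viability[viability["duration_days"] > 0]
    for cell, grp in viability.groupby("cell"):
        durations = np.sort(grp["duration_days"].unique())
        if concentration is None:
            common = None
            for d in durations:
                concs = set(grp.loc[grp["duration_days"] == d, "concentration"])
                common = concs if common is None else common & concs
            common = {c for c in (common or set()) if c > 0}
            if not common:
                raise ValueError(f"no common positive concentration for {cell}")
            conc = max(common)
        else:
            conc = concentration
        inh = []
        for d in durations:
            sel = grp[(grp["duration_days"] == d) & (grp["concentration"] == conc)]
            if sel.empty:
                raise ValueError(f"missing duration {d} at {conc} for {cell}")
            inh.append(100.0 - float(sel["viability_pct"].mean()))
        inh = np.maximum(np.asarray(inh, float), floor)
        out[cell] = ToxVector(cell, durations.astype(float), inh,
                              zscore(np.log10(inh)))
    return out


def _log10_zscore_rows(areas: pd.DataFrame) -> pd.DataFrame:
    """Per-row log10 transform then Z-score, the toxicity-correlation scale."""
    logz = np.log10(np.maximum(areas.to_numpy(float), 1e-12))
    sd = logz.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    logz = (logz - logz.mean(axis=1, keepdims=True)) / sd
    return pd.DataFrame(logz, index=areas.index, columns=areas.columns)


def associate_toxicity(
    kin: KineticsMatrix,
    tox: Mapping[str, ToxVector],
    alpha: float = 0.05,
    net: Optional[ProductNetwork] = None,
) -> dict[str, set]:
    """Product-cell associations: Pearson r > 0 with two-tailed p < alpha.

    Product kinetics are re-expressed like the toxicity vectors (log10 of
    area, then Z-score) before correlation.  When a network is given, cell
    nodes and product-cell edges are added to it.  Returns the per-cell
    associated product id sets.
    """
    cells = sorted(tox)
    for c in cells:
        if len(tox[c].z) != kin.z.shape[1]:
            raise ValueError("toxicity vector and kinetics timepoint grids differ")
    logz = _log10_zscore_rows(kin.areas).to_numpy(float)
    assoc: dict[str, set] = {c: set() for c in cells}
    if net is not None:
        for c in cells:
            net.graph.add_node(c, kind="cell")
    for row, pid in zip(logz, kin.areas.index):
        for c in cells:
            r, p = pearson_r_p(row, tox[c].z)
            if r > 0 and p < alpha:
                assoc[c].add(pid)
                if net is not None:
                    net.graph.add_edge(pid, c, weight=r, p=p)
    return assoc


def community_toxicity(
    kin: KineticsMatrix,
    net: ProductNetwork,
    tox: Mapping[str, ToxVector],
) -> pd.DataFrame:
    """Community x cell Pearson correlation of mean community kinetics.

    The community profile is the mean of its members' normalized kinetics
    rows on the same scale the toxicity correlation uses (log10 area,
    Z-scored); only reported communities (>10 nodes) are included.
    """
    if not net.reported:
        raise ValueError("no reported communities")
    cells = sorted(tox)
    logz = _log10_zscore_rows(kin.areas)
    rows = {}
    for label in net.reported:
        members = [p for p, lab in net.communities.items()
                   if lab == label and p in kin.z.index]
        profile = logz.loc[members].to_numpy(float).mean(axis=0)
        rows[label] = [pearson_r_p(profile, tox[c].z)[0] for c in cells]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cells).sort_index()


def venn_summary(sets: Mapping[str, Iterable]) -> dict[str, int]:
    """Three-set Venn region counts plus the union size.

    Keys: "<A> only", pairwise "<A>&<B>", "all", "union" (order-stable over
    the sorted set names).  Satisfies inclusion-exclusion exactly.
    """
    names = sorted(sets)
    if len(names) != 3:
        raise ValueError("venn_summary expects exactly 3 sets")
    a, b, c = (set(sets[n]) for n in names)
    out = {
        f"{names[0]} only": len(a - b - c),
        f"{names[1]} only": len(b - a - c),
        f"{names[2]} only": len(c - a - b),
        f"{names[0]}&{names[1]}": len((a & b) - c),
        f"{names[0]}&{names[2]}": len((a & c) - b),
        f"{names[1]}&{names[2]}": len((b & c) - a),
        "all": len(a & b & c),
        "union": len(a | b | c),
    }
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_network(net: ProductNetwork, path: str, fmt: Optional[str] = None) -> None:
    """Write a Gephi-compatible GEXF (default) or GraphML file."""
    fmt = fmt or ("graphml" if str(path).endswith(".graphml") else "gexf")
    g = net.graph.copy()
    for n, d in g.nodes(data=True):
        d.setdefault("kind", "product")
        if n in net.communities:
            d["community"] = int(net.communities[n])
    if fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path: str) -> ProductNetwork:
    """Re-import a network written by :func:`export_network`."""
    if str(path).endswith(".graphml"):
        g = nx.read_graphml(path)
    else:
        g = nx.read_gexf(path)
    communities = {n: int(d["community"]) for n, d in g.nodes(data=True)
                   if "community" in d}
    sizes: dict[int, int] = {}
    for lab in communities.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    reported = sorted(l for l, s in sizes.items() if s >= 11)
    return ProductNetwork(g, communities, reported)
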