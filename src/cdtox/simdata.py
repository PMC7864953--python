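"""Seeded synthetic-data generators with planted ground truth.

Every input the two analysis engines consume can be generated here, with a
truth table recording what was planted, so each downstream stage is
testable without any external download:

* ``simulate_counts``      - RHT-style amplicon count matrix: ~1200 genes,
  seven fivefold dilutions plus four vehicle controls, single replicate,
  negative-binomial counts, a planted fraction of genes following
  sigmoidal / linear / U-shaped concentration-effect curves with known ECs.
* ``simulate_peak_table``  - nontarget peak table over irradiation
  timepoints {0.5, 1, 4, 8} days with planted kinetic archetypes (the
  community structure), control-dominated decoys, and products whose
  kinetics are collinear with per-cell-line toxicity vectors.
* ``simulate_msms``        - MGF spectra with diagnostic aromatic fragments
  ([C7H7]+ / [C6H5]+) and PEG-ladder precursors planted.
* ``simulate_viability``   - optical-density plates from a log-logistic
  inhibition truth whose potency increases with irradiation duration.
* ``simulate_assoc_table`` - chemical-gene association tables with planted
  hits (>50% coverage of a DEG reference set) and decoys.

All generators are pure functions of (config, seed): identical
configuration gives byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import dilution_series, peg_mass
from .dose_response import FOLD_CHANGE_THRESHOLD

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_counts",
    "simulate_sigmoid_profiles",
    "simulate_peak_table",
    "simulate_msms",
    "simulate_viability",
    "simulate_assoc_table",
    "viability_table",
    "write_mgf",
    "write_gmt",
    "simulate_gene_sets",
    "CELL_LINES",
    "ARCHETYPES_LOG10",
]

CELL_LINES = ("HEK-293", "HeLa", "HepG2")

# Kinetic archetypes as log10 peak area over timepoints {0.5, 1, 4, 8} d.
# The first three are collinear (in log space) with the cell-line toxicity
# vectors; the rest are neutral shapes (rise-fall, decay, early spike).
ARCHETYPES_LOG10: tuple[np.ndarray, ...] = (
    np.array([0.5, 1.5, 3.0, 3.8]),   # saturating rise  (HEK-293-tied)
    np.array([0.2, 0.4, 1.2, 3.8]),   # late rise        (HeLa-tied)
    np.array([1.2, 2.2, 3.2, 3.6]),   # steady rise      (HepG2-tied)
    np.array([1.0, 2.5, 3.6, 2.0]),   # rise then fall
    np.array([3.5, 3.0, 1.5, 0.5]),   # decay
    np.array([0.8, 3.2, 1.5, 0.8]),   # early spike
)

_INH_MIN_PCT = 2.0    # inhibition mapped into [2, 95] percent
_INH_MAX_PCT = 95.0
_HILL = 1.5
_TOX_CONC = 300.0     # mg carbon/L at which toxicity vectors are defined


@dataclass
class SimConfig:
    """Study-design parameters for all generators (defaults = study layout)."""

    seed: int = 0
    # transcriptome
    n_genes: int = 1200
    deg_fraction: float = 0.1
    curve_type_mix: dict = field(default_factory=lambda: {
        "sigmoidal": 0.5, "linear": 0.3, "u_shaped": 0.2})
    dispersion: float = 0.1
    library_size_range: tuple = (543_084, 5_848_694)
    concentrations: tuple = tuple(sorted(dilution_series(300.0, 5.0, 7)))
    n_vehicle: int = 4
    baseline_sigma: float = 1.2
    # peak table
    n_products: int = 300
    n_communities: int = 4
    decoy_fraction: float = 0.1
    kinetic_noise_cv: float = 0.05
    toxic_fraction: float = 0.2
    timepoints: tuple = (0.5, 1.0, 4.0, 8.0)
    n_peg: int = 9          # PEG ladder members n = 3 .. 3 + n_peg - 1
    n_aromatic: int = 16
    # viability plates
    viability_concentrations: tuple = (0.0, 10.0, 30.0, 100.0, 300.0)
    n_replicates: int = 6
    od_blank: float = 0.08
    od_control: float = 0.90
    od_noise_sd: float = 0.005
    # association screen
    n_hit_chemicals: int = 5
    n_decoy_chemicals: int = 10

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.concentrations) < 2:
            raise ValueError("at least 2 concentrations required")
        if len(set(self.concentrations)) != len(self.concentrations) \
                or any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be distinct and positive")
        if not math.isclose(sum(self.curve_type_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("curve_type_mix must sum to 1")
        if not 0 <= self.deg_fraction <= 1:
            raise ValueError("deg_fraction must be in [0, 1]")
        if len(self.timepoints) < 3:
            raise ValueError("at least 3 timepoints required")
        if self.n_communities > len(ARCHETYPES_LOG10):
            raise ValueError(
                f"only {len(ARCHETYPES_LOG10)} kinetic archetypes available")


@dataclass
class TruthTable:
    """Planted ground truth for all generators."""

    genes: Optional[pd.DataFrame] = None      # is_deg, curve_type, true_ec, ...
    products: Optional[pd.DataFrame] = None   # community, is_decoy, tox flags,
                                              # formula, peg_n, is_aromatic
    chemicals: Optional[pd.DataFrame] = None  # coverage, passes
    cell_inhibition: Optional[pd.DataFrame] = None  # cell x timepoint truth

    def to_json(self, path: str) -> None:
        payload = {}
        for name in ("genes", "products", "chemicals", "cell_inhibition"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = json.loads(df.to_json(orient="split"))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# cell-line truth shared by peak-table and viability generators
# ---------------------------------------------------------------------------

def _cell_inhibition_truth(cfg: SimConfig) -> pd.DataFrame:
    """Percent inhibition per cell line over irradiated durations.

    Each cell line's log10 inhibition is an affine image of its kinetic
    archetype, so planted toxic products are exactly collinear (in log
    space) with the toxicity vector; inhibition spans [2, 95] percent.
    """
    rows = {}
    for ci, cell in enumerate(CELL_LINES):
        a = ARCHETYPES_LOG10[ci]
        lo, hi = math.log10(_INH_MIN_PCT), math.log10(_INH_MAX_PCT)
        beta = (hi - lo) / (a.max() - a.min())
        alpha = lo - beta * a.min()
        rows[cell] = 10.0 ** (alpha + beta * a)
    return pd.DataFrame(rows, index=list(cfg.timepoints)).T


def _ec50_from_inhibition(inh_pct: np.ndarray) -> np.ndarray:
    """Invert the log-logistic at the reference concentration."""
    inh = np.clip(inh_pct, 1e-6, 100 - 1e-6)
    return _TOX_CONC * ((100.0 - inh) / inh) ** (1.0 / _HILL)


# ---------------------------------------------------------------------------
# transcriptome counts
# ---------------------------------------------------------------------------

def _planted_curves(cfg: SimConfig, rng: np.random.Generator):
    """Draw per-DEG generating curves and their analytic true ECs."""
    x = np.log10(np.asarray(cfg.concentrations))
    x_min, x_max = x.min(), x.max()
    span = x_max - x_min
    n_deg = int(round(cfg.n_genes * cfg.deg_fraction))
    types = rng.choice(list(cfg.curve_type_mix),
                       p=list(cfg.curve_type_mix.values()), size=n_deg)
    thr = FOLD_CHANGE_THRESHOLD
    curves = []
    for ct in types:
        sign = rng.choice([-1.0, 1.0])
        if ct == "sigmoidal":
            amp = sign * rng.uniform(1.5, 3.0)
            mid = rng.uniform(x_min + 0.15 * span, x_max - 0.15 * span)
            slope = rng.uniform(1.5, 3.0)
            fn = (lambda xx, a=amp, m=mid, s=slope:
                  a / (1.0 + np.exp(-s * (xx - m))))
            true_ec = 10.0 ** mid
        elif ct == "linear":
            b = sign * rng.uniform(0.4, 1.2)
            fn = (lambda xx, b=b, x0=x_min: b * (xx - x0))
            true_ec = 10.0 ** (x_min + thr / abs(b))
        else:  # u_shaped
            depth = sign * rng.uniform(1.5, 3.0)
            x_v = rng.uniform(x_min + 0.45 * span, x_min + 0.75 * span)
            w = x_v - x_min
            fn = (lambda xx, d=depth, xv=x_v, ww=w:
                  d * (((xx - xv) / ww) ** 2 - 1.0))
            true_ec = 10.0 ** (x_v - w * math.sqrt(1.0 - thr / abs(depth)))
        curves.append((ct, fn, true_ec))
    return curves


def simulate_sigmoid_profiles(
    n_genes: int,
    noise_sd: float,
    seed: int,
    concentrations: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted sigmoidal fold-change profiles with Gaussian noise.

    Draws amplitudes, midpoints and slopes from the same distributions as
    the count generator's sigmoidal curves (|amplitude| 1.5-3 log2 units,
    slope 1.5-3 per decade, midpoint in the inner 70% of the tested range)
    and returns (fc matrix [n_genes x n_conc], log10 concentrations,
    true EC vector).
    """
    rng = np.random.default_rng(seed)
    conc = np.sort(np.asarray(
        concentrations if concentrations is not None
        else dilution_series(300.0, 5.0, 7)))
    x = np.log10(conc)
    span = x.max() - x.min()
    fc = np.empty((n_genes, len(x)))
    true_ec = np.empty(n_genes)
    for i in range(n_genes):
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 3.0)
        mid = rng.uniform(x.min() + 0.15 * span, x.max() - 0.15 * span)
        slope = rng.uniform(1.5, 3.0)
        fc[i] = amp / (1.0 + np.exp(-slope * (x - mid))) + rng.normal(0, noise_sd, len(x))
        true_ec[i] = 10.0 ** mid
    return fc, x, true_ec


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate the RHT count matrix, sample sheet and gene truth table.

    One replicate per concentration plus ``n_vehicle`` vehicle controls.
    Null genes are flat in expectation; planted genes follow their
    generating curve on the log2 fold-change scale, realized as
    negative-binomial counts scaled by per-sample library size.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    conc = np.asarray(sorted(cfg.concentrations))
    x = np.log10(conc)

    baseline = rng.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=cfg.n_genes)
    weights = baseline / baseline.sum()

    curves = _planted_curves(cfg, rng)
    n_deg = len(curves)
    deg_idx = rng.choice(cfg.n_genes, size=n_deg, replace=False)

    # log2 fold change per gene x treated sample
    lfc = np.zeros((cfg.n_genes, len(conc)))
    for (ct, fn, _), gi in zip(curves, deg_idx):
        lfc[gi] = fn(x)

    sample_ids = [f"T{j+1:02d}" for j in range(len(conc))] + \
                 [f"V{j+1:02d}" for j in range(cfg.n_vehicle)]
    concentrations = list(conc) + [0.0] * cfg.n_vehicle
    is_vehicle = [False] * len(conc) + [True] * cfg.n_vehicle
    lib_lo, lib_hi = cfg.library_size_range
    lib_sizes = rng.integers(lib_lo, lib_hi + 1, size=len(sample_ids))

    counts = np.zeros((cfg.n_genes, len(sample_ids)), dtype=np.int64)
    for sj, lib in enumerate(lib_sizes):
        mult = 2.0 ** lfc[:, sj] if sj < len(conc) else np.ones(cfg.n_genes)
        w = weights * mult
        mu = lib * w / w.sum()
        lam = rng.gamma(shape=1.0 / cfg.dispersion,
                        scale=mu * cfg.dispersion)
        counts[:, sj] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    samples_df = pd.DataFrame({
        "concentration": concentrations,
        "is_vehicle": is_vehicle,
    }, index=pd.Index(sample_ids, name="sample_id"))

    truth = pd.DataFrame({
        "is_deg": False, "curve_type": None, "true_ec": np.nan,
    }, index=pd.Index(genes, name="gene"))
    for (ct, _, ec), gi in zip(curves, deg_idx):
        truth.iloc[gi] = [True, ct, ec]
    return counts_df, samples_df, TruthTable(genes=truth)


# ---------------------------------------------------------------------------
# peak table
# ---------------------------------------------------------------------------

def _community_sizes(cfg: SimConfig, n_planted: int) -> list[int]:
    n_tox = min(3, cfg.n_communities)
    fracs = [cfg.toxic_fraction] * n_tox
    rest = max(1.0 - sum(fracs), 0.0)
    n_neutral = cfg.n_communities - n_tox
    fracs += [rest / n_neutral] * n_neutral if n_neutral else []
    total = sum(fracs)
    sizes = [int(round(f / total * n_planted)) for f in fracs]
    sizes[-1] += n_planted - sum(sizes)
    return sizes


def simulate_peak_table(cfg: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Generate a long-format nontarget peak table with planted structure.

    Products are drawn from ``n_communities`` kinetic archetypes with
    multiplicative lognormal noise (CV ``kinetic_noise_cv``); planted
    products get a control area low enough to pass the 3x detection rule
    with a 10% margin at every timepoint, decoys a control area high enough
    to always fail it.  The first three archetypes are collinear with the
    cell-line toxicity vectors, so their members are cytotoxicity-
    associated by construction; per-cell truth flags are computed from the
    noiseless archetype-vs-toxicity correlation.
    """
    from .kinetics_net import pearson_r_p  # local import avoids a cycle

    rng = np.random.default_rng(cfg.seed + 1)
    tps = list(cfg.timepoints)
    n_decoy = int(round(cfg.n_products * cfg.decoy_fraction))
    n_planted = cfg.n_products - n_decoy
    sizes = _community_sizes(cfg, n_planted)

    inh = _cell_inhibition_truth(cfg)
    cell_z = {c: _z(np.log10(inh.loc[c].to_numpy())) for c in CELL_LINES}

    # per-community truth flags from the noiseless archetype
    comm_flags = {}
    for k in range(cfg.n_communities):
        az = _z(ARCHETYPES_LOG10[k][: len(tps)])
        comm_flags[k] = {
            c: (lambda rp: rp[0] > 0 and rp[1] < 0.05)(pearson_r_p(az, cell_z[c]))
            for c in CELL_LINES}

    rows = []
    truth_rows = []
    pid = 0
    sigma_ln = cfg.kinetic_noise_cv

    def product_id(i: int) -> str:
        return f"P{i:04d}"

    mz_specs = _mass_plan(cfg, rng)

    for k, size in enumerate(sizes):
        base_log = ARCHETYPES_LOG10[k][: len(tps)]
        for _ in range(size):
            name = product_id(pid)
            scale = 10.0 ** rng.uniform(2.0, 3.0)  # per-product abundance
            areas = scale * 10.0 ** base_log * np.exp(
                rng.normal(0.0, sigma_ln, len(tps)))
            control = areas.min() / (3.0 * 1.1)  # pass 3x rule with margin
            spec = mz_specs.get(pid, {})
            mz = spec.get("mz", float(rng.uniform(100.0, 600.0)))
            rt = float(rng.uniform(1.0, 20.0))
            rows.append((name, mz, rt, "control", control, np.nan))
            for t, a in zip(tps, areas):
                rows.append((name, mz, rt, f"i{t:g}", a, t))
            truth_rows.append({
                "product": name, "community": k + 1, "is_decoy": False,
                **{f"tox_{c}": comm_flags[k][c] for c in CELL_LINES},
                "formula": spec.get("formula"), "peg_n": spec.get("peg_n"),
                "is_aromatic": spec.get("is_aromatic", False),
            })
            pid += 1

    for _ in range(n_decoy):
        name = product_id(pid)
        k = int(rng.integers(0, cfg.n_communities))
        scale = 10.0 ** rng.uniform(2.0, 3.0)
        areas = scale * 10.0 ** ARCHETYPES_LOG10[k][: len(tps)] * np.exp(
            rng.normal(0.0, sigma_ln, len(tps)))
        control = areas.max() / (3.0 * 0.9)  # fail 3x rule with margin
        mz = float(rng.uniform(100.0, 600.0))
        rt = float(rng.uniform(1.0, 20.0))
        rows.append((name, mz, rt, "control", control, np.nan))
        for t, a in zip(tps, areas):
            rows.append((name, mz, rt, f"i{t:g}", a, t))
        truth_rows.append({
            "product": name, "community": 0, "is_decoy": True,
            **{f"tox_{c}": False for c in CELL_LINES},
            "formula": None, "peg_n": None, "is_aromatic": False,
        })
        pid += 1

    peaks = pd.DataFrame(rows, columns=[
        "peak_id", "mz", "rt", "sample", "area", "timepoint_days"])
    truth = pd.DataFrame(truth_rows).set_index("product")
    return peaks, TruthTable(products=truth, cell_inhibition=inh)


def _z(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _mass_plan(cfg: SimConfig, rng: np.random.Generator) -> dict[int, dict]:
    """Assign PEG-ladder and aromatic identities to the first planted ids."""
    proton = 1.007276
    plan: dict[int, dict] = {}
    i = 0
    for j in range(cfg.n_peg):
        n = 3 + j
        plan[i] = {"mz": peg_mass(n) + proton,
                   "formula": f"C{2*n}H{4*n+2}O{n+1}", "peg_n": n}
        i += 1
    aromatic_formulas = ["C12H14", "C13H14", "C14H14", "C24H24"]
    arom_masses = {"C12H14": 158.109550, "C13H14": 170.109550,
                   "C14H14": 182.109550, "C24H24": 312.187801}
    for j in range(cfg.n_aromatic):
        f = aromatic_formulas[j % len(aromatic_formulas)]
        plan[i] = {"mz": arom_masses[f] + proton, "formula": f,
                   "is_aromatic": True}
        i += 1
    return plan


# ---------------------------------------------------------------------------
# MS/MS spectra
# ---------------------------------------------------------------------------

def simulate_msms(cfg: SimConfig, truth: TruthTable) -> list[dict]:
    """MGF-style spectra for the products carrying planted structure.

    Aromatic products contain the diagnostic fragments m/z 91.0542
    ([C7H7]+) and/or 77.0386 ([C6H5]+); PEG-ladder products carry their
    ladder precursor plus repeat-unit loss fragments.  Remaining planted
    products get uninformative noise peaks.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    proton = 1.007276
    spectra = []
    prods = truth.products
    for name, row in prods[~prods["is_decoy"]].iterrows():
        peg_n = row.get("peg_n")
        peg_n = int(peg_n) if peg_n is not None and not pd.isna(peg_n) else None
        frag_mz: list[float] = []
        if row.get("is_aromatic"):
            frag_mz.append(91.05423)
            if rng.random() < 0.5:
                frag_mz.append(77.03858)
            precursor = 91.05423
        elif peg_n is not None:
            pm = peg_mass(peg_n)
            precursor = pm + proton
            frag_mz.extend(precursor - k * 44.026215
                           for k in range(1, min(peg_n, 3)))
        else:
            continue
        frag_mz += list(rng.uniform(50.0, 250.0, 3))  # uninformative peaks
        frag_mz = sorted(frag_mz)
        spectra.append({
            "params": {"title": name, "pepmass": (float(precursor), None),
                       "charge": "1+"},
            "m/z array": np.asarray(frag_mz, float),
            "intensity array": rng.uniform(1e3, 1e5, len(frag_mz)),
        })
    return spectra


def write_mgf(spectra: Sequence[dict], path: str) -> None:
    """Write spectra in the standard BEGIN IONS / END IONS MGF dialect."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec['params']['title']}\n")
            pep = spec["params"]["pepmass"]
            fh.write(f"PEPMASS={pep[0]:.5f}\n")
            fh.write(f"CHARGE={spec['params']['charge']}\n")
            for mz, inten in zip(spec["m/z array"], spec["intensity array"]):
                fh.write(f"{mz:.5f} {inten:.1f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# viability plates
# ---------------------------------------------------------------------------

def simulate_viability(cfg: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Optical-density plates per cell line x irradiation duration.

    The truth is a two-parameter log-logistic inhibition curve per cell and
    duration whose EC50 decreases with irradiation time (consistent with
    the cell-inhibition truth shared with the peak-table generator);
    Gaussian noise is added on the OD scale.  Includes control
    (concentration 0) and blank (no cells) wells.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    inh = _cell_inhibition_truth(cfg)
    rows = []
    durations = [0.0] + list(cfg.timepoints)
    for cell in CELL_LINES:
        ec50s = {0.0: np.inf}
        ec50_irr = _ec50_from_inhibition(inh.loc[cell].to_numpy())
        ec50s.update(dict(zip(cfg.timepoints, ec50_irr)))
        for d in durations:
            ec50 = ec50s[d]
            for conc in cfg.viability_concentrations:
                if conc == 0 or not np.isfinite(ec50):
                    v = 100.0
                else:
                    v = 100.0 / (1.0 + (conc / ec50) ** _HILL)
                for rep in range(cfg.n_replicates):
                    od = cfg.od_blank + (cfg.od_control - cfg.od_blank) * v / 100.0
                    od += rng.normal(0.0, cfg.od_noise_sd)
                    kind = "control" if conc == 0 else "treated"
                    rows.append((cell, d, conc, rep + 1, kind, max(od, 0.0)))
            for rep in range(cfg.n_replicates):
                od = cfg.od_blank + rng.normal(0.0, cfg.od_noise_sd)
                rows.append((cell, d, np.nan, rep + 1, "blank", max(od, 0.0)))
    od_df = pd.DataFrame(rows, columns=[
        "cell", "duration_days", "concentration", "replicate", "well_type", "od"])
    return od_df, TruthTable(cell_inhibition=inh)


def viability_table(od_df: pd.DataFrame) -> pd.DataFrame:
    """Relative viability (percent) per cell x duration x concentration.

    Applies the OD arithmetic 100 x (treated - blank)/(control - blank) on
    replicate means.
    """
    out = []
    for (cell, d), grp in od_df.groupby(["cell", "duration_days"]):
        blank = grp.loc[grp["well_type"] == "blank", "od"].mean()
        control = grp.loc[grp["well_type"] == "control", "od"].mean()
        for conc, g2 in grp[grp["well_type"] == "treated"].groupby("concentration"):
            v = 100.0 * (g2["od"].mean() - blank) / (control - blank)
            out.append((cell, d, conc, v))
        out.append((cell, d, 0.0, 100.0 * (control - blank) / (control - blank)))
    return pd.DataFrame(out, columns=[
        "cell", "duration_days", "concentration", "viability_pct"])


# ---------------------------------------------------------------------------
# gene sets and chemical associations
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    cfg: SimConfig,
    truth: TruthTable,
    n_terms: int = 50,
    seed_responsive: int = 15,
) -> dict[str, list[str]]:
    """Random gene sets (10-40 genes); the first ``seed_responsive`` terms
    are seeded with at least three planted DEGs so pathway aggregation has
    guaranteed responsive terms."""
    rng = np.random.default_rng(cfg.seed + 4)
    genes = list(truth.genes.index)
    degs = list(truth.genes.index[truth.genes["is_deg"]])
    sets: dict[str, list[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(10, 41))
        members = set(rng.choice(genes, size=size, replace=False))
        if i < seed_responsive and len(degs) >= 3:
            members |= set(rng.choice(degs, size=min(5, len(degs)), replace=False))
        sets[f"TERM:{i:04d}"] = sorted(members)
    return sets


def write_gmt(sets: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for tid, members in sets.items():
            fh.write("\t".join([tid, "synthetic term"] + list(members)) + "\n")


def simulate_assoc_table(
    cfg: SimConfig,
    reference_degs: Sequence[str],
) -> tuple[pd.DataFrame, TruthTable]:
    """Chemical-gene association table with planted screen hits and decoys.

    Hit chemicals cover a strict majority (55-90%) of the reference DEG
    set; decoys cover at most half (strictly fewer than 50% plus one
    exact-boundary decoy at 50% when the set size is even).
    """
    rng = np.random.default_rng(cfg.seed + 5)
    ref = list(reference_degs)
    if not ref:
        raise ValueError("reference DEG set must be non-empty")
    n = len(ref)
    rows = []
    truth_rows = []
    for i in range(cfg.n_hit_chemicals):
        k = max(int(math.floor(n * rng.uniform(0.55, 0.9))), n // 2 + 1)
        hit = rng.choice(ref, size=min(k, n), replace=False)
        chem = f"HIT:{i:02d}"
        rows += [(chem, "gene", g) for g in hit]
        truth_rows.append({"chemical": chem, "coverage": len(hit) / n,
                           "passes": len(hit) / n > 0.5})
    for i in range(cfg.n_decoy_chemicals):
        k = int(math.floor(n * rng.uniform(0.1, 0.5)))
        if i == 0 and n % 2 == 0:
            k = n // 2  # exact 50% boundary: must fail the strict screen
        hit = rng.choice(ref, size=max(k, 1), replace=False)
        chem = f"DECOY:{i:02d}"
        rows += [(chem, "gene", g) for g in hit]
        truth_rows.append({"chemical": chem, "coverage": len(hit) / n,
                           "passes": len(hit) / n > 0.5})
    assoc = pd.DataFrame(rows, columns=["chemical_id", "target_type", "target_id"])
    truth = pd.DataFrame(truth_rows).set_index("chemical")
    return assoc, TruthTable(chemicals=truth)
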