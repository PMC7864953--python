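"""Orchestration of the two analysis workflows plus the ``cdtox`` CLI.

``run_rht`` composes fold change -> nine-model fitting -> DEG calling ->
pathway potency -> log-normal potency curves -> chemical screen.
``run_kinetics`` composes product detection -> kinetics Z-scoring ->
correlation network -> Louvain communities -> toxicity association ->
community-cell clustering -> annotation -> Gephi export.

Both are deterministic given a configuration and seed; every stage logs
counts in/out so the analysis funnel is auditable, and each run writes a
manifest (config, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import click
import numpy as np
import pandas as pd

from . import __version__
from .dose_response import CountMatrix, analyze_counts
from .pathway_potency import (
    map_degs_to_terms, potency_distribution, read_gmt, screen_chemicals,
    TermMap,
)
from .kinetics_net import (
    PeakTable, associate_toxicity, build_kinetics, community_toxicity,
    correlation_network, detect_products, export_network,
    louvain_communities, toxicity_vectors, venn_summary,
)
from .msannot import (
    annotate_products, assign_formula, detect_homologues, fragment_frequency,
    read_mgf,
)
from .simdata import (
    SimConfig, simulate_assoc_table, simulate_counts, simulate_gene_sets,
    simulate_msms, simulate_peak_table, simulate_viability, viability_table,
    write_gmt, write_mgf,
)

log = logging.getLogger("cdtox")


@dataclass
class RunConfig:
    """All stage parameters for both workflows."""

    seed: int = 0
    alpha_deg: float = 0.05
    normalize: bool = True
    pseudocount: float = 0.5
    min_matched_degs: int = 3
    screen_threshold: float = 0.5
    detect_ratio: float = 3.0
    p_edge: float = 0.001
    alpha_tox: float = 0.05
    min_community: int = 11
    louvain_resolution: float = 1.0
    formula_tol_ppm: float = 10.0
    homologue_tol_da: float = 0.002
    fragment_tol_da: float = 0.005
    fragment_min_count: int = 5

    def manifest(self) -> dict:
        cfg = asdict(self)
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
        return {"config": cfg, "config_hash": digest, "version": __version__}


def _write_manifest(cfg: RunConfig, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cfg.manifest(), fh, indent=1)


# ---------------------------------------------------------------------------
# RHT workflow
# ---------------------------------------------------------------------------

def run_rht(
    cm: CountMatrix,
    term_maps: Optional[list[TermMap]] = None,
    assoc: Optional[pd.DataFrame] = None,
    config: Optional[RunConfig] = None,
    outdir: Optional[str] = None,
) -> dict:
    """Full RHT analysis: DEGs, pathway ECs, potency curves, screen.

    Returns a dict with keys ``degs`` (records), ``summary`` (per-gene
    frame), ``pathway_ecs``, ``potency`` (level -> PotencyCurve) and
    ``screen`` (None without an association table).
    """
    config = config or RunConfig()
    log.info("RHT: %d genes, %d samples", *cm.counts.shape)
    degs, summary = analyze_counts(
        cm, alpha=config.alpha_deg, pseudocount=config.pseudocount,
        normalize=config.normalize, seed=config.seed)
    log.info("RHT: %d DEGs called at alpha=%g", len(degs), config.alpha_deg)
    deg_ecs = {d.gene: d.ec for d in degs}

    pathway_rows = []
    for tm in term_maps or []:
        hits = map_degs_to_terms(deg_ecs, tm, min_matched=config.min_matched_degs)
        log.info("RHT: %d responsive %s terms", len(hits), tm.ontology)
        pathway_rows += [{
            "term": h.term, "ontology": h.ontology,
            "n_matched": len(h.matched_degs), "ec": h.ec,
        } for h in hits]
    pathway_df = pd.DataFrame(
        pathway_rows, columns=["term", "ontology", "n_matched", "ec"])

    potency = {}
    if len(deg_ecs) >= 5:
        potency["DEG"] = potency_distribution(list(deg_ecs.values()), "DEG")
    for ont in pathway_df["ontology"].unique():
        ecs = pathway_df.loc[pathway_df["ontology"] == ont, "ec"]
        if len(ecs) >= 5:
            potency[ont] = potency_distribution(ecs.to_numpy(), ont)

    screen = None
    if assoc is not None and deg_ecs:
        screen = screen_chemicals(assoc, set(deg_ecs),
                                  threshold=config.screen_threshold)
        log.info("screen: %d/%d chemicals pass",
                 int(screen["passes"].sum()), len(screen))

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_manifest(config, out)
        pd.DataFrame([d.as_dict() for d in degs]).to_csv(
            out / "degs.csv", index=False)
        summary.to_csv(out / "gene_summary.csv")
        pathway_df.to_csv(out / "pathway_ec.csv", index=False)
        curves = []
        for level, pc in potency.items():
            for rank, (pos, ec) in enumerate(
                    zip(pc.plotting_positions, pc.ecs), start=1):
                curves.append((level, rank, ec, pos, float(pc.cdf(ec))))
        pd.DataFrame(curves, columns=[
            "level", "rank", "ec", "plotting_position", "fitted_cdf",
        ]).to_csv(out / "potency_curves.csv", index=False)
        if screen is not None:
            screen.to_csv(out / "screen.csv", index=False)
    return {"degs": degs, "summary": summary, "pathway_ecs": pathway_df,
            "potency": potency, "screen": screen}


# ---------------------------------------------------------------------------
# kinetics workflow
# ---------------------------------------------------------------------------

def run_kinetics(
    peaks: PeakTable,
    viability: pd.DataFrame,
    spectra: Optional[dict] = None,
    config: Optional[RunConfig] = None,
    outdir: Optional[str] = None,
) -> dict:
    """Full formation-kinetics workflow from a peak table and viability data.

    ``viability`` is a tidy table (cell, duration_days, concentration,
    viability_pct); ``spectra`` maps product id -> MGF spectrum dict.
    """
    config = config or RunConfig()
    n_peaks = peaks.data["peak_id"].nunique()
    detected, zero_ctrl = detect_products(peaks, ratio=config.detect_ratio)
    n_detected = len(set.union(*detected.values())) if detected else 0
    log.info("kinetics: %d peaks -> %d detected products (%d zero-control flagged)",
             n_peaks, n_detected, len(zero_ctrl))
    if n_detected == 0:
        return {"kinetics": None, "network": None, "assoc": {}, "venn": None,
                "community_cell": None, "annotations": [],
                "funnel": {"peaks": n_peaks, "detected": 0}}
    kin = build_kinetics(peaks, detected)
    log.info("kinetics: %d products at all timepoints (%d constant dropped)",
             kin.z.shape[0], len(kin.dropped_constant))
    net = correlation_network(kin, p_threshold=config.p_edge)
    n_correlated = sum(1 for n in net.product_nodes if net.graph.degree(n) > 0)
    log.info("network: %d/%d correlated products, %d edges",
             n_correlated, kin.z.shape[0], net.graph.number_of_edges())
    net = louvain_communities(net, min_size=config.min_community,
                              seed=config.seed,
                              resolution=config.louvain_resolution)
    log.info("network: %d reported communities (>%d nodes)",
             len(net.reported), config.min_community - 1)
    tox = toxicity_vectors(viability)
    assoc = associate_toxicity(kin, tox, alpha=config.alpha_tox, net=net)
    for cell in sorted(assoc):
        log.info("association: %d products for %s", len(assoc[cell]), cell)
    venn = venn_summary(assoc)
    comm_cell = community_toxicity(kin, net, tox) if net.reported else None

    associated = sorted(set.union(*assoc.values())) if assoc else []
    mz_map = peaks.mz_of()
    annotations = []
    if associated:
        cands = {pid: assign_formula(float(mz_map[pid]),
                                     tol_ppm=config.formula_tol_ppm)
                 for pid in associated}
        neutral = {pid: float(mz_map[pid]) - 1.007276 for pid in associated}
        series = detect_homologues(neutral, tol_da=config.homologue_tol_da)
        spectra = spectra or {}
        annotations = annotate_products(
            {pid: float(mz_map[pid]) for pid in associated},
            cands, series, spectra=spectra,
            frag_tol_da=config.fragment_tol_da)
        log.info("annotation: %d products annotated, %d homologue series",
                 len(annotations), len(series))

    funnel = {"peaks": n_peaks, "detected": n_detected,
              "kinetics": int(kin.z.shape[0]), "correlated": n_correlated,
              "edges": net.graph.number_of_edges(),
              "communities_reported": len(net.reported),
              "associated": len(associated)}

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_manifest(config, out)
        export_network(net, str(out / "network.gexf"))
        export_network(net, str(out / "network.graphml"))
        node_rows = [{
            "product": pid,
            "community": net.communities.get(pid, 0),
            **{f"assoc_{c}": pid in assoc[c] for c in sorted(assoc)},
        } for pid in net.product_nodes]
        pd.DataFrame(node_rows).to_csv(out / "nodes.csv", index=False)
        edge_rows = [{"source": u, "target": v, **d}
                     for u, v, d in net.graph.edges(data=True)]
        pd.DataFrame(edge_rows).to_csv(out / "edges.csv", index=False)
        pd.Series(venn).to_csv(out / "venn.csv", header=["count"])
        if comm_cell is not None:
            comm_cell.to_csv(out / "community_cell.csv")
        if annotations:
            pd.DataFrame([{
                "product": a.product,
                "formula": a.formula.hill if a.formula else None,
                "ppm": a.formula.ppm if a.formula else np.nan,
                "rdbe": a.formula.rdbe if a.formula else np.nan,
                "series": a.series, "group": a.group,
                "fragments": ";".join(a.diagnostic_fragments),
                "confidence": a.confidence,
            } for a in annotations]).to_csv(out / "annotations.csv", index=False)
        with open(out / "funnel.json", "w") as fh:
            json.dump(funnel, fh, indent=1)

    return {"kinetics": kin, "network": net, "assoc": assoc, "venn": venn,
            "community_cell": comm_cell, "annotations": annotations,
            "funnel": funnel}


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log stage funnels to stderr.")
def cli(verbose: bool) -> None:
    """Carbon-dot photodegradation cytotoxicity analysis toolkit."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        stream=sys.stderr, format="%(name)s %(levelname)s %(message)s")


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-genes", type=int, default=1200, show_default=True)
@click.option("--n-products", type=int, default=300, show_default=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
def simulate(seed: int, n_genes: int, n_products: int, outdir: str) -> None:
    """Generate a full synthetic study (counts, peaks, MGF, plates, truth)."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_products=n_products)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts, samples, gene_truth = simulate_counts(cfg)
    counts.to_csv(out / "counts.tsv", sep="\t")
    samples.rename(columns={"concentration": "concentration_mg_per_L"}) \
        .to_csv(out / "samples.csv")
    peaks, peak_truth = simulate_peak_table(cfg)
    peaks.to_csv(out / "peaks.csv", index=False)
    od, _ = simulate_viability(cfg)
    od.to_csv(out / "od_plates.csv", index=False)
    viability_table(od).to_csv(out / "viability.csv", index=False)
    write_mgf(simulate_msms(cfg, peak_truth), str(out / "spectra.mgf"))
    gene_sets = simulate_gene_sets(cfg, gene_truth)
    write_gmt(gene_sets, str(out / "terms.gmt"))
    degs = list(gene_truth.genes.index[gene_truth.genes["is_deg"]])
    if degs:
        assoc, chem_truth = simulate_assoc_table(cfg, degs)
        assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
        gene_truth.chemicals = chem_truth.chemicals
    gene_truth.products = peak_truth.products
    gene_truth.cell_inhibition = peak_truth.cell_inhibition
    gene_truth.to_json(str(out / "truth.json"))
    click.echo(f"wrote synthetic study to {out}")


@cli.command()
@click.option("--counts", type=click.Path(exists=True), required=True)
@click.option("--samples", type=click.Path(exists=True), required=True)
@click.option("--gmt", type=click.Path(exists=True), default=None)
@click.option("--assoc", type=click.Path(exists=True), default=None)
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--no-normalize", is_flag=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
def rht(counts, samples, gmt, assoc, alpha, no_normalize, seed, outdir) -> None:
    """Run the RHT dose-response + pathway potency workflow."""
    cm = CountMatrix.from_files(counts, samples)
    config = RunConfig(seed=seed, alpha_deg=alpha, normalize=not no_normalize)
    term_maps = [read_gmt(gmt)] if gmt else None
    assoc_df = pd.read_csv(assoc, sep="\t") if assoc else None
    res = run_rht(cm, term_maps=term_maps, assoc=assoc_df,
                  config=config, outdir=outdir)
    click.echo(f"{len(res['degs'])} DEGs; outputs in {outdir}")


@cli.command()
@click.option("--peaks", type=click.Path(exists=True), required=True)
@click.option("--viability", type=click.Path(exists=True), required=True)
@click.option("--mgf", type=click.Path(exists=True), default=None)
@click.option("--p-edge", type=float, default=0.001, show_default=True)
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--min-community", type=int, default=11, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
def kinet(peaks, viability, mgf, p_edge, alpha, min_community, seed, outdir) -> None:
    """Run the formation-kinetics network + annotation workflow."""
    pt = PeakTable.from_csv(peaks)
    via = pd.read_csv(viability)
    spectra = None
    if mgf:
        spectra = {s["params"]["title"]: s for s in read_mgf(mgf)}
    config = RunConfig(seed=seed, p_edge=p_edge, alpha_tox=alpha,
                       min_community=min_community)
    res = run_kinetics(pt, via, spectra=spectra, config=config, outdir=outdir)
    click.echo(json.dumps(res["funnel"]))


@cli.command()
@click.option("--mgf", type=click.Path(exists=True), required=True)
@click.option("--tol-da", type=float, default=0.005, show_default=True)
@click.option("--min-count", type=int, default=5, show_default=True)
@click.option("--out", "outpath", type=click.Path(), required=True)
def annotate(mgf, tol_da, min_count, outpath) -> None:
    """Mine high-frequency fragments from an MGF spectrum collection."""
    spectra = read_mgf(mgf)
    stats = fragment_frequency(spectra, tol_da=tol_da, min_count=min_count)
    pd.DataFrame([{"mz": s.mz, "count": s.count} for s in stats]) \
        .to_csv(outpath, index=False)
    click.echo(f"{len(stats)} high-frequency fragments -> {outpath}")


@cli.command()
@click.option("--run-dir", type=click.Path(exists=True), required=True)
def report(run_dir) -> None:
    """Print the funnel/manifest summary of a previous run."""
    out = Path(run_dir)
    for name in ("manifest.json", "funnel.json"):
        p = out / name
        if p.exists():
            click.echo(p.read_text())


def main() -> None:  # pragma: no cover
    try:
        cli(standalone_mode=False)
    except click.UsageError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    except Exception as exc:  # noqa: BLE001
        click.echo(f"internal error: {exc}", err=True)
        sys.exit(2)


if __name__ == "__main__":  # pragma: no cover
    main()
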