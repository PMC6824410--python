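"""Integration of the three scans: sharing, overlap annotation, pipeline.

Multi-breed sharing of ancestry-excess regions is reported in two explicit
modes, because "shared" admits two defensible readings:

* ``strict-intersection`` -- maximal breed subsets whose intervals have a
  common point; the combined interval is [max(starts), min(ends)];
* ``chained-overlap`` -- connected components of the interval-overlap graph;
  the combined interval is the component hull [min(starts), max(ends)].

Overlap annotation lists, per region, the significant F_ST SNPs (per
comparison) and ROH islands it physically intersects, using closed 1-based
intervals throughout (a shared boundary base pair counts as overlap).
``run_pipeline`` orchestrates QC -> ancestry scans -> F_ST scans ->
consensus regions -> ROH islands -> sharing/annotation, writing TSV outputs
and a manifest that records every configurable decision.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io as gio
from . import synthetic_data as synth
from .fst_outlier import (AlleleCountTable, MCMC_PRESETS, McmcConfig,
                          bayescan_scan, build_outlier_regions, consensus_counts)
from .local_ancestry import (SignalRegion, compute_maa, estimate_alpha,
                             maa_signal_regions, regions_to_frame,
                             window_ancestry)
from .roh_islands import (IslandTrack, call_islands, cross_breed_island_overlaps,
                          detect_roh, snp_roh_incidence)

__all__ = [
    "SharedRegionReport",
    "OverlapAnnotation",
    "shared_regions",
    "annotate_overlaps",
    "run_pipeline",
]


@dataclass
class SharedRegionReport:
    """A region supported by several breeds on one chromosome."""

    chromosome: int
    mode: str                                   # strict-intersection | chained-overlap
    breeds: tuple[str, ...]
    sources: dict[str, list[tuple[int, int]]]   # breed -> contributing intervals
    combined: tuple[int, int]

    def __post_init__(self):
        if self.mode not in ("strict-intersection", "chained-overlap"):
            raise ValueError(f"unknown sharing mode {self.mode!r}")
        if self.mode == "strict-intersection":
            s, e = self.combined
            if s > e:
                raise ValueError("strict-mode combined interval is empty")
            for ivs in self.sources.values():
                for a, b in ivs:
                    if not (a <= s and e <= b):
                        raise ValueError("combined interval escapes a contributor")


@dataclass
class OverlapAnnotation:
    """Cross-method evidence inside one region."""

    region: SignalRegion
    fst_hits: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    island_hits: list[tuple[str, int, int, int]] = field(default_factory=list)

    @property
    def has_fst_overlap(self) -> bool:
        return any(self.fst_hits.values())

    @property
    def has_island_overlap(self) -> bool:
        return bool(self.island_hits)


def _interval(r: SignalRegion) -> tuple[int, int]:
    return (r.start_bp, r.end_bp)


def shared_regions(per_breed_regions: dict[str, list[SignalRegion]],
                   min_breeds: int = 3, mode: str = "strict-intersection",
                   ) -> list[SharedRegionReport]:
    """Regions supported by at least ``min_breeds`` breeds, per chromosome.

    Strict mode enumerates, per chromosome, every maximal set of intervals
    with a common point (the maximal cliques of the interval graph, found at
    interval start points) and keeps those touching >= ``min_breeds``
    distinct breeds.  Chained mode keeps connected components of the
    interval-overlap graph touching >= ``min_breeds`` breeds.
    """
    if min_breeds < 2:
        raise ValueError("min_breeds must be >= 2")
    if min_breeds > len(per_breed_regions):
        raise ValueError("min_breeds exceeds the number of breeds")
    items = [(breed, r) for breed, regs in per_breed_regions.items()
             for r in regs]
    reports: list[SharedRegionReport] = []
    for c in sorted({r.chromosome for _, r in items}):
        on_c = [(breed, r) for breed, r in items if r.chromosome == c]
        if mode == "strict-intersection":
            reports += _strict_cliques(c, on_c, min_breeds)
        elif mode == "chained-overlap":
            reports += _chained_components(c, on_c, min_breeds)
        else:
            raise ValueError(f"unknown sharing mode {mode!r}")
    return reports


def _strict_cliques(chromosome, on_c, min_breeds):
    cliques: list[tuple[frozenset, list]] = []
    for _, anchor in on_c:
        p = anchor.start_bp     # every maximal clique is active at some start
        active = [(breed, r) for breed, r in on_c
                  if r.start_bp <= p <= r.end_bp]
        key = frozenset(id(r) for _, r in active)
        if all(key != k for k, _ in cliques):
            cliques.append((key, active))
    # keep only maximal cliques (not contained in a larger one)
    maximal = [(k, a) for k, a in cliques
               if not any(k < other for other, _ in cliques)]
    out = []
    for _, active in maximal:
        breeds = tuple(sorted({breed for breed, _ in active}))
        if len(breeds) < min_breeds:
            continue
        start = max(r.start_bp for _, r in active)
        end = min(r.end_bp for _, r in active)
        sources: dict[str, list[tuple[int, int]]] = {}
        for breed, r in active:
            sources.setdefault(breed, []).append(_interval(r))
        out.append(SharedRegionReport(int(chromosome), "strict-intersection",
                                      breeds, sources, (int(start), int(end))))
    return out


def _chained_components(chromosome, on_c, min_breeds):
    n = len(on_c)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if on_c[i][1].overlaps(on_c[j][1]):
            parent[find(i)] = find(j)
    comps: dict[int, list] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(on_c[i])
    out = []
    for members in comps.values():
        breeds = tuple(sorted({breed for breed, _ in members}))
        if len(breeds) < min_breeds:
            continue
        start = min(r.start_bp for _, r in members)
        end = max(r.end_bp for _, r in members)
        sources: dict[str, list[tuple[int, int]]] = {}
        for breed, r in members:
            sources.setdefault(breed, []).append(_interval(r))
        out.append(SharedRegionReport(int(chromosome), "chained-overlap",
                                      breeds, sources, (int(start), int(end))))
    return out


def annotate_overlaps(regions: list[SignalRegion],
                      fst_results: dict[str, pd.DataFrame] | None = None,
                      island_tracks: list[IslandTrack] | None = None,
                      q_threshold: float = 0.05) -> list[OverlapAnnotation]:
    """Cross-method annotation of each region (closed-interval containment).

    ``fst_results`` maps a comparison label to a frame with columns
    ``snp_id``, ``chromosome``, ``position_bp`` and ``q_value``; SNPs with
    q < ``q_threshold`` lying inside a region (boundaries included) are
    listed per comparison.  Islands sharing >= 1 bp with the region are
    listed as (breed, start, end).
    """
    annotations = []
    for region in regions:
        ann = OverlapAnnotation(region)
        for label, df in (fst_results or {}).items():
            sig = df[df["q_value"] < q_threshold]
            inside = sig[(sig["chromosome"] == region.chromosome)
                         & (sig["position_bp"] >= region.start_bp)
                         & (sig["position_bp"] <= region.end_bp)]
            ann.fst_hits[label] = list(zip(inside["snp_id"], inside["position_bp"]))
        for track in island_tracks or []:
            for c, s, e, _n in track.islands:
                if (c == region.chromosome and s <= region.end_bp
                        and region.start_bp <= e):
                    ann.island_hits.append((track.breed, c, s, e))
        annotations.append(ann)
    return annotations


# ---------------------------------------------------------------------------
# Pipeline orchestration


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the input fingerprint."""


def _fingerprint(dataset: gio.GenotypeDataset) -> str:
    return (f"{dataset.n_samples}x{dataset.n_snps}"
            f"/miss={dataset.n_missing}")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full multi-cohort scan described by ``config``.

    The config either names PLINK input files plus breed roles, or a
    ``simulation`` section from which all cohorts are generated.  Results
    are returned as a dict of in-memory objects; when ``out_dir`` (or
    ``config['out_dir']``) is set, TSV tracks, a markdown report, and a
    key=value manifest are written there.  Fully deterministic given
    ``config['seed']``.
    """
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir or config.get("out_dir")) if (out_dir or
                                                         config.get("out_dir")) else None
    manifest: dict[str, object] = {"seed": seed}
    bundle: dict[str, object] = {"manifest": manifest}

    # ---- stage: inputs -----------------------------------------------------
    sim_cfg = config.get("simulation")
    try:
        if sim_cfg:
            spec = synth.AncestralPanelSpec(
                n_snps_per_chrom=int(sim_cfg.get("n_snps_per_chrom", 1000)),
                n_chromosomes=int(sim_cfg.get("n_chromosomes", 1)),
                spacing_bp=int(sim_cfg.get("spacing_bp", 50_000)),
                fst=float(sim_cfg.get("fst", 0.1)))
            panel, snp_map = synth.simulate_ancestral_panels(
                spec, int(rng.integers(2**31 - 1)))
            manifest["simulation"] = sim_cfg
            bundle["panel"] = panel
        else:
            dataset = gio.read_plink(config["ped"], config.get("map"))
            qc_cfg = config.get("qc", {})
            dataset, qc_report = gio.qc_filter(
                dataset, mind=float(qc_cfg.get("mind", 0.1)),
                geno=float(qc_cfg.get("geno", 0.01)),
                maf=float(qc_cfg.get("maf", 0.005)))
            bundle["dataset"], bundle["qc_report"] = dataset, qc_report
            manifest["qc"] = {"mind": qc_report.mind, "geno": qc_report.geno,
                              "maf": qc_report.maf,
                              "input_fingerprint": _fingerprint(dataset)}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage=input: {exc}") from exc

    anc_cfg = config.get("ancestry", {})
    fst_cfg = config.get("fst", {})
    roh_cfg = config.get("roh", {})
    int_cfg = config.get("integrate", {})

    # ---- stage: ancestry scans --------------------------------------------
    per_breed_regions: dict[str, list[SignalRegion]] = {}
    maa_tracks = {}
    try:
        scenarios = []
        if sim_cfg:
            for k, sc in enumerate(sim_cfg.get("admixed_cohorts", [])):
                cohort, truth = synth.simulate_admixed_cohort(
                    panel, n=int(sc.get("n", 50)), alpha=float(sc.get("alpha", 0.7)),
                    g=float(sc.get("g", 7)), r=float(sc.get("r", 1e-8)),
                    excess_loci=sc.get("excess_loci"),
                    delta=float(sc.get("delta", 0.0)),
                    seed=int(rng.integers(2**31 - 1)))
                scenarios.append((sc.get("name", f"Cohort{k + 1}"), cohort, panel))
                bundle.setdefault("admixture_truth", {})[
                    sc.get("name", f"Cohort{k + 1}")] = truth
        else:
            for sc in anc_cfg.get("scenarios", []):
                sub = dataset.subset(dataset.samples_of(sc["admixed_breed"]))
                pnl = gio.panel_from_breeds(dataset, sc["merino_breed"],
                                            sc["other_breed"])
                scenarios.append((sc["admixed_breed"], sub, pnl))
        for name, cohort, pnl in scenarios:
            alphas, alpha_mean = estimate_alpha(cohort, pnl)
            dos = window_ancestry(
                cohort, pnl, alpha_mean,
                g=float(anc_cfg.get("g", 7)), r=float(anc_cfg.get("r", 1e-8)),
                window_snps=int(anc_cfg.get("window_snps", 50)),
                n_offsets=int(anc_cfg.get("n_offsets", 5)))
            track = compute_maa(dos, cohort.snp_map)
            regs = maa_signal_regions(
                track, top_frac=float(anc_cfg.get("top_frac", 0.05)),
                merge_gap_bp=int(anc_cfg.get("merge_gap_bp", 5_000_000)))
            per_breed_regions[name] = regs
            maa_tracks[name] = track
            manifest.setdefault("alpha_mean", {})[name] = alpha_mean
    except Exception as exc:
        raise StageError(f"stage=ancestry: {exc}") from exc
    bundle["ancestry_regions"] = per_breed_regions
    bundle["maa_tracks"] = maa_tracks

    # ---- stage: F_ST scans -------------------------------------------------
    mcmc: McmcConfig = MCMC_PRESETS[fst_cfg.get("mcmc_preset", "desk")]
    result_sets, fst_frames = [], {}
    cons_map = None
    try:
        pairs = []
        if sim_cfg:
            for k, pc in enumerate(sim_cfg.get("fst_pairs", [])):
                pair_spec = replace(spec,
                                    fst=float(pc.get("neutral_fst", spec.fst)))
                pair_ds, truth = synth.simulate_differentiated_pair(
                    pair_spec, n_per_pop=int(pc.get("n_per_pop", 50)),
                    outlier_indices=pc.get("outlier_indices"),
                    outlier_fst=float(pc.get("outlier_fst", 0.5)),
                    seed=int(rng.integers(2**31 - 1)))
                pairs.append((pc.get("name", f"Pair{k + 1}"),
                              AlleleCountTable.from_dataset(pair_ds, "PopA", "PopB")))
                bundle.setdefault("outlier_truth", {})[
                    pc.get("name", f"Pair{k + 1}")] = truth
        else:
            for pc in fst_cfg.get("pairs", []):
                label = f"{pc['merino']}_vs_{pc['other']}"
                pairs.append((label, AlleleCountTable.from_dataset(
                    dataset, pc["merino"], pc["other"])))
        for label, counts in pairs:
            results = bayescan_scan(counts, mcmc,
                                    seed=int(rng.integers(2**31 - 1)))
            result_sets.append(results)
            df = counts.snp_map.to_frame()
            df["q_value"] = [r.q_value for r in results]
            df["pip"] = [r.pip for r in results]
            df["fst"] = [r.fst_posterior_mean for r in results]
            fst_frames[label] = df
            cons_map = counts.snp_map
    except Exception as exc:
        raise StageError(f"stage=fst: {exc}") from exc
    consensus = outlier_regions = None
    if result_sets:
        consensus = consensus_counts(result_sets, cons_map,
                                     float(fst_cfg.get("q_threshold", 0.05)))
        outlier_regions = build_outlier_regions(
            consensus, seed_min=int(fst_cfg.get("seed_min", 4)),
            link_dist_bp=int(fst_cfg.get("link_dist_bp", 200_000)))
    bundle["fst_results"] = fst_frames
    bundle["consensus"] = consensus
    bundle["outlier_regions"] = outlier_regions
    manifest["fst"] = {"preset": fst_cfg.get("mcmc_preset", "desk"),
                       "q_threshold": fst_cfg.get("q_threshold", 0.05),
                       "seed_min": fst_cfg.get("seed_min", 4),
                       "link_dist_bp": fst_cfg.get("link_dist_bp", 200_000)}

    # ---- stage: ROH --------------------------------------------------------
    island_tracks = []
    try:
        roh_cohorts = []
        if sim_cfg and sim_cfg.get("roh"):
            rc = sim_cfg["roh"]
            roh_ds, roh_truth = synth.simulate_roh_cohort(
                snp_map, n=int(rc.get("n", 20)),
                tract_specs=rc.get("tracts"),
                background_het=float(rc.get("background_het", 0.4)),
                seed=int(rng.integers(2**31 - 1)))
            roh_cohorts.append(("RohSim", roh_ds))
            bundle["roh_truth"] = roh_truth
        elif not sim_cfg:
            for breed in roh_cfg.get("breeds", dataset.breeds()):
                roh_cohorts.append((breed,
                                    dataset.subset(dataset.samples_of(breed))))
        all_segments = {}
        for breed, cohort in roh_cohorts:
            segs = detect_roh(
                cohort, min_snps=int(roh_cfg.get("min_snps", 25)),
                min_length_bp=int(roh_cfg.get("min_length_bp", 500_000)),
                max_gap_bp=int(roh_cfg.get("max_gap_bp", 250_000)),
                density_bp=int(roh_cfg.get("density_bp", 100_000)))
            inc = snp_roh_incidence(segs, cohort.snp_map, cohort.n_samples)
            island_tracks.append(call_islands(
                inc, cohort.snp_map, breed,
                percentile=float(roh_cfg.get("island_percentile", 0.999))))
            all_segments[breed] = segs
    except Exception as exc:
        raise StageError(f"stage=roh: {exc}") from exc
    bundle["roh_segments"] = all_segments
    bundle["island_tracks"] = island_tracks
    bundle["island_overlaps"] = (cross_breed_island_overlaps(island_tracks)
                                 if len(island_tracks) >= 2 else [])

    # ---- stage: integration ------------------------------------------------
    try:
        min_breeds = int(int_cfg.get("min_breeds", 3))
        mode = int_cfg.get("mode", "strict-intersection")
        bundle["shared_regions"] = (
            shared_regions(per_breed_regions, min_breeds, mode)
            if len(per_breed_regions) >= min_breeds else [])
        all_regions = [r for regs in per_breed_regions.values() for r in regs]
        if outlier_regions:
            all_regions += outlier_regions
        bundle["annotations"] = annotate_overlaps(
            all_regions, fst_frames, island_tracks,
            q_threshold=float(fst_cfg.get("q_threshold", 0.05)))
        manifest["integrate"] = {"min_breeds": min_breeds, "mode": mode}
    except Exception as exc:
        raise StageError(f"stage=integrate: {exc}") from exc

    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, track in bundle.get("maa_tracks", {}).items():
        track.to_frame().to_csv(out_dir / f"maa_{name}.tsv", sep="\t", index=False)
    rows = [(b,) + tuple(regions_to_frame([r]).iloc[0])
            for b, regs in bundle.get("ancestry_regions", {}).items()
            for r in regs]
    pd.DataFrame(rows, columns=["breed", "chromosome", "start_bp", "end_bp",
                                "start_snp_id", "end_snp_id", "score",
                                "n_snps"]).to_csv(
        out_dir / "ancestry_regions.tsv", sep="\t", index=False)
    for label, df in bundle.get("fst_results", {}).items():
        df.to_csv(out_dir / f"fst_{label}.tsv", sep="\t", index=False)
    if bundle.get("consensus") is not None:
        bundle["consensus"].to_frame().to_csv(out_dir / "consensus.tsv",
                                              sep="\t", index=False)
    if bundle.get("outlier_regions"):
        regions_to_frame(bundle["outlier_regions"]).to_csv(
            out_dir / "outlier_regions.tsv", sep="\t", index=False)
    for track in bundle.get("island_tracks", []):
        track.islands_frame().to_csv(out_dir / f"islands_{track.breed}.tsv",
                                     sep="\t", index=False)
    shared = bundle.get("shared_regions", [])
    pd.DataFrame(
        [(r.chromosome, r.mode, ";".join(r.breeds), r.combined[0], r.combined[1])
         for r in shared],
        columns=["chromosome", "mode", "breeds", "start_bp", "end_bp"],
    ).to_csv(out_dir / "shared_regions.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.txt", "w") as fh:
        for key, val in sorted(bundle["manifest"].items()):
            fh.write(f"{key}={json.dumps(val, sort_keys=True, default=str)}\n")
    with open(out_dir / "report.md", "w") as fh:
        fh.write("# merinoscan run report\n\n")
        fh.write(f"- ancestry cohorts: {len(bundle.get('maa_tracks', {}))}\n")
        fh.write(f"- pair-wise F_ST comparisons: {len(bundle.get('fst_results', {}))}\n")
        fh.write(f"- ROH island tracks: {len(bundle.get('island_tracks', []))}\n")
        fh.write(f"- shared regions: {len(shared)}\n")
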