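"""End-to-end orchestration: simulate/load -> telomeres -> enrichment ->
centromere calls -> satellites -> clusters -> phasing -> LTR dynamics ->
report.

Every stage writes its outputs under the configured directory as it
completes and registers itself in MANIFEST.json, so a failed run leaves the
completed prefix behind.  All TSV/JSON/BED/bedGraph/FASTA outputs are
deterministic given (config, seed); the plain-text log additionally records
wall times and is the only non-reproducible file.

The per-chromosome report mirrors the standard centromere table: chromosome
size, centromere location and size (Mb, one decimal), and the satellite
("CentFs") array span attributed to each centromere.  Satellite arrays
extend beyond the CENH3-enriched core, so the array span is summed over a
configurable flank (default +/-2 Mb) around each call; raw values are kept
in the JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as clu
from . import enrichment as enr
from . import ltr as ltrmod
from . import phasing as pha
from . import satellites as sat
from . import synth
from . import telomere as tel
from .core import (
    Genome,
    GenomicInterval,
    read_fasta,
    read_fragments_bed,
    write_bedgraph,
    write_fasta,
    write_json,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # --- simulation (used when no FASTA input is given) ---
    simulate: bool = True
    n_chromosomes: int = 3
    chromosome_length: int = 2_000_000
    monomer_length: int = 356
    satellite_mutation_rate: float = 0.02
    telomere_copies: int = 200
    cen_start_fraction: float = 0.485
    cen_end_fraction: float = 0.515
    ltr_per_chromosome: int = 2
    ltr_length: int = 400
    ltr_internal_length: int = 2000
    ltr_mutation_load: float = 0.01
    n_input: int = 20_000
    n_chip: int = 20_000
    chip_centromere_fraction: float = 0.6
    phase_positions: list[int] | None = field(default_factory=lambda: [50, 200])
    phase_sd: float = 10.0
    fragment_length: float = 150.0
    # --- real inputs (override simulation) ---
    fasta: str | None = None
    chip_bed: str | None = None
    input_bed: str | None = None
    # --- enrichment / calling ---
    window_size: int = 20_000
    pseudocount: float = 1.0
    min_log2: float = 1.0
    min_windows: int = 3
    merge_gap: int = 1
    # --- clusters ---
    cluster_reads: int = 5000
    read_length: int = 150
    ratio_min: float = 7.0
    proportion_min: float = 0.0005
    # --- phasing ---
    phasing_bandwidth: float = 5.0
    phasing_min_prominence: float = 0.25
    phasing_min_separation: int = 40
    phasing_min_identity: float = 0.8
    phasing_max_fragments: int = 5000
    # --- LTR dating ---
    mutation_rate_per_year: float = 1.3e-8
    k_correction: str = "raw"
    # --- reporting ---
    report_flank: int = 2_000_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # where results land is not part of the analysis
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _simulation_specs(cfg: PipelineConfig, rng: np.random.Generator
                      ) -> list[synth.ChromosomeSpec]:
    monomer = synth.decode(synth._motif_free_seq(rng, cfg.monomer_length, 0.36))
    specs = []
    for i in range(cfg.n_chromosomes):
        L = cfg.chromosome_length
        cen = (int(cfg.cen_start_fraction * L), int(cfg.cen_end_fraction * L))
        ltrs = []
        for j in range(cfg.ltr_per_chromosome):
            pos = int(L * (0.12 + 0.18 * j))
            ltrs.append(synth.LTRInsertionSpec(
                pos, cfg.ltr_length, cfg.ltr_internal_length,
                cfg.ltr_mutation_load))
        specs.append(synth.ChromosomeSpec(
            name=f"chr{i + 1}", length=L,
            telomere_copies_5p=cfg.telomere_copies,
            telomere_copies_3p=cfg.telomere_copies,
            centromere=cen, satellite_monomer=monomer,
            satellite_mutation_rate=cfg.satellite_mutation_rate,
            ltr_insertions=ltrs,
        ))
    return specs


def render_centromere_table(calls: list[enr.CentromereCall],
                            families: list[sat.SatelliteFamily],
                            genome: Genome,
                            flank: int = 2_000_000) -> pd.DataFrame:
    """Per-chromosome report: sizes in Mb at one decimal; the satellite-array
    column sums family arrays overlapping a +/-flank window around the
    (primary) centromere call."""
    primary = {c.chrom: c for c in calls if c.primary}
    rows = []
    for chrom in genome.names:
        row: dict[str, object] = {
            "chrom": chrom,
            "chr_size_mb": round(genome[chrom].length / 1e6, 1),
        }
        call = primary.get(chrom)
        if call is None:
            row.update({"cen_location_mb": "", "cen_size_mb": "",
                        "centfs_arrays_mb": ""})
        else:
            probe = GenomicInterval(chrom, max(0, call.interval.start - flank),
                                    call.interval.end + flank)
            span = sum(probe.overlap(a.interval)
                       for fam in families for a in fam.arrays)
            row.update({
                "cen_location_mb": (f"{call.interval.start / 1e6:.1f}-"
                                    f"{call.interval.end / 1e6:.1f}"),
                "cen_size_mb": round(call.size_mb, 1),
                "centfs_arrays_mb": round(span / 1e6, 1),
            })
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "chr_size_mb",
                                       "cen_location_mb", "cen_size_mb",
                                       "centfs_arrays_mb"])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the MANIFEST dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                      "stages": {}}

    log_handler = logging.FileHandler(out / "pipeline.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    logger.info("run start seed=%d config_hash=%s", cfg.seed, cfg.config_hash())

    def stage_done(name: str, t0: float, status: str = "completed") -> None:
        manifest["stages"][name] = status
        logger.info("stage %s: %s (%.1fs)", name, status, time.time() - t0)
        write_json(manifest, out / "MANIFEST.json")

    try:
        # ------------------------------------------------------------------
        t0 = time.time()
        if cfg.fasta is not None:
            genome = read_fasta(cfg.fasta)
            truth = None
            chip = (read_fragments_bed(cfg.chip_bed, genome, "chip")
                    if cfg.chip_bed else None)
            inp = (read_fragments_bed(cfg.input_bed, genome, "input")
                   if cfg.input_bed else None)
        else:
            rng = np.random.default_rng(cfg.seed)
            specs = _simulation_specs(cfg, rng)
            genome, truth = synth.build_genome(specs, cfg.seed)
            if cfg.n_chip > 0 and cfg.n_input > 0:
                chip, inp = synth.simulate_fragments(
                    genome, truth, cfg.n_input, cfg.n_chip,
                    cfg.chip_centromere_fraction, cfg.fragment_length,
                    cfg.phase_positions, cfg.phase_sd, seed=cfg.seed)
            else:
                chip = inp = None
            if chip is not None:
                synth.write_fixture(genome, truth, chip, inp, out)
            else:
                write_fasta(genome, out / "genome.fa")
                write_json(truth.to_dict(), out / "truth.json")
        stage_done("acquire", t0)

        # ------------------------------------------------------------------
        t0 = time.time()
        reports = []
        for c in genome.names:
            r5, r3 = tel.count_telomere_repeats(genome[c])
            reports += [r5, r3]
        table, n_present = tel.telomere_table(reports)
        table.to_csv(out / "telomeres.tsv", sep="\t", index=False)
        write_json({"telomeres_present": n_present}, out / "telomere_summary.json")
        stage_done("telomeres", t0)

        # ------------------------------------------------------------------
        calls: list[enr.CentromereCall] = []
        if chip is not None and inp is not None:
            t0 = time.time()
            chip_track = enr.compute_window_density(chip, genome, cfg.window_size)
            inp_track = enr.compute_window_density(inp, genome, cfg.window_size)
            ratio = enr.enrichment_ratio(chip_track, inp_track, cfg.pseudocount)
            write_bedgraph(chip_track.to_bedgraph_rows(), out / "chip_density.bedgraph")
            write_bedgraph(inp_track.to_bedgraph_rows(), out / "input_density.bedgraph")
            write_bedgraph(ratio.to_bedgraph_rows("log2"), out / "log2_ratio.bedgraph")
            stage_done("enrich", t0)

            t0 = time.time()
            calls = enr.call_centromeres(ratio, cfg.min_log2, cfg.min_windows,
                                         cfg.merge_gap)
            enr.calls_to_table(calls).to_csv(out / "centromeres.tsv", sep="\t",
                                             index=False, float_format="%.6g")
            primary = [c for c in calls if c.primary]
            if primary:
                summary = enr.centromere_summary(
                    [c.size_mb for c in primary], genome.total_length / 1e6)
                write_json({"report": summary.report(),
                            "raw": {"total_mb": summary.total_mb,
                                    "mean_mb": summary.mean_mb,
                                    "percent_of_genome": summary.percent_of_genome}},
                           out / "centromere_summary.json")
            stage_done("callcen", t0)
        else:
            stage_done("enrich", time.time(), "skipped")
            stage_done("callcen", time.time(), "skipped")

        # ------------------------------------------------------------------
        t0 = time.time()
        arrays: list[sat.SatelliteArray] = []
        for c in genome.names:
            arrays += sat.find_tandem_arrays(genome[c])
        families = sat.classify_families(arrays)
        sat.arrays_to_table(arrays).to_csv(out / "satellite_arrays.tsv",
                                           sep="\t", index=False,
                                           float_format="%.6g")
        with open(out / "families.fa", "w") as fh:
            for fam in families:
                fh.write(f">{fam.name}\n{fam.consensus}\n")
        if calls:
            comp = sat.centromere_composition(calls, families)
            comp.to_csv(out / "composition.tsv", sep="\t", index=False,
                        float_format="%.6g")
        stage_done("satellites", t0)

        # ------------------------------------------------------------------
        if chip is not None and inp is not None and families:
            t0 = time.time()
            repeat_clusters = [clu.RepeatCluster(f.name, f.consensus, "satellite")
                               for f in families]
            chip_reads = clu.sample_reads(chip, genome, cfg.cluster_reads,
                                          cfg.read_length, seed=cfg.seed)
            input_reads = clu.sample_reads(inp, genome, cfg.cluster_reads,
                                           cfg.read_length, seed=cfg.seed + 1)
            cc, _ = clu.align_reads_to_clusters(chip_reads, repeat_clusters)
            ic, _ = clu.align_reads_to_clusters(input_reads, repeat_clusters)
            enrich = clu.cluster_enrichment_ratio(cc, ic, len(chip_reads),
                                                  len(input_reads))
            selected = clu.select_centromeric_clusters(enrich, cfg.ratio_min,
                                                       cfg.proportion_min)
            pd.DataFrame([vars(e) for e in enrich]).to_csv(
                out / "clusters.tsv", sep="\t", index=False,
                float_format="%.6g")
            write_json({"selected": selected}, out / "clusters_selected.json")
            stage_done("clusters", t0)
        else:
            stage_done("clusters", time.time(), "skipped")

        # ------------------------------------------------------------------
        if chip is not None and inp is not None and families:
            t0 = time.time()
            fam = families[0]
            trimer = pha.make_trimer(fam.consensus)
            phase_out = {}
            for fs, src in ((chip, "chip"), (inp, "input")):
                seqs = _fragment_seqs_in_arrays(fs, genome, fam,
                                                cfg.phasing_max_fragments)
                mids, _ = pha.map_fragments_to_trimer(seqs, trimer,
                                                      cfg.phasing_min_identity)
                profile = pha.fold_to_monomer(mids, len(fam.consensus),
                                              bandwidth=cfg.phasing_bandwidth,
                                              family=fam.name, source=src)
                peaks = pha.call_phase_peaks(profile,
                                             cfg.phasing_min_prominence,
                                             cfg.phasing_min_separation)
                pd.DataFrame({
                    "position": np.arange(profile.monomer_length),
                    "count": profile.counts,
                    "smoothed": profile.smoothed,
                }).to_csv(out / f"phasing_{src}.tsv", sep="\t", index=False,
                          float_format="%.6g")
                phase_out[src] = {"peaks": peaks.positions,
                                  "n_mapped": profile.n_mapped,
                                  "n_retained": profile.n_retained}
                if src == "chip":
                    chip_profile = profile
                else:
                    phase_out["concordance"] = pha.phase_concordance(
                        chip_profile, profile)
            write_json(phase_out, out / "phasing_peaks.json")
            stage_done("phasing", t0)
        else:
            stage_done("phasing", time.time(), "skipped")

        # ------------------------------------------------------------------
        t0 = time.time()
        elements: list[ltrmod.LTRElement] = []
        for c in genome.names:
            elements += ltrmod.find_ltr_pairs(genome[c])
        params = ltrmod.DatingParams(cfg.mutation_rate_per_year,
                                     cfg.k_correction)
        ltrmod.date_elements(elements, params)
        if calls:
            ltrmod.classify_by_centromere(elements, calls)
        if len(elements) >= 2:
            seqs = [genome[e.element.chrom]
                    .sequence[e.element.start:e.element.end]
                    for e in elements]
            ltrmod.cluster_clades(elements, seqs)
        ltrmod.elements_to_table(elements).to_csv(
            out / "ltr_elements.tsv", sep="\t", index=False,
            float_format="%.6g")
        ltr_summary: dict = {"n_elements": len(elements),
                             "dating": {"r": params.r,
                                        "correction": params.correction}}
        if calls and elements:
            ltr_summary["populations"] = ltrmod.compare_populations(elements)
        write_json(ltr_summary, out / "ltr_summary.json")

        if chip is not None and inp is not None:
            feats: dict[str, list[GenomicInterval]] = {
                "satellite": [a.interval for fam in families for a in fam.arrays],
                "cen_ltr": [e.element for e in elements
                            if e.location_class == "centromeric"],
                "noncen_ltr": [e.element for e in elements
                               if e.location_class == "non_centromeric"],
            }
            fe = enr.feature_enrichment(chip, inp, feats, cfg.pseudocount)
            write_json({k: {"chip": v.chip_count, "input": v.input_count,
                            "log2_ratio": v.log2_ratio}
                        for k, v in fe.items()},
                       out / "feature_enrichment.json")
        stage_done("ltr", t0)

        # ------------------------------------------------------------------
        t0 = time.time()
        table = render_centromere_table(calls, families, genome, cfg.report_flank)
        table.to_csv(out / "centromere_table.tsv", sep="\t", index=False)
        stage_done("report", t0)
    except Exception as err:
        failed = len(manifest["stages"])
        stage_name = ["acquire", "telomeres", "enrich", "callcen",
                      "satellites", "clusters", "phasing", "ltr", "report"]
        name = stage_name[min(failed, len(stage_name) - 1)]
        logger.error("stage %s failed: %s", name, err)
        manifest["failed_stage"] = name
        write_json(manifest, out / "MANIFEST.json")
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    return manifest


def _fragment_seqs_in_arrays(fragments, genome: Genome,
                             family: sat.SatelliteFamily, cap: int
                             ) -> list[str]:
    """Sequences of fragments whose midpoints fall in the family's arrays
    (first ``cap`` in coordinate order, deterministic)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for a in family.arrays:
        by_chrom.setdefault(a.interval.chrom, []).append(
            (a.interval.start, a.interval.end))
    seqs: list[str] = []
    for c in sorted(by_chrom):
        if c not in fragments.by_chrom:
            continue
        s, e = fragments.by_chrom[c]
        mids = (s + e) // 2
        keep = np.zeros(len(mids), dtype=bool)
        for a, b in by_chrom[c]:
            keep |= (mids >= a) & (mids < b)
        order = np.argsort(s[keep], kind="stable")
        for a, b in zip(s[keep][order].tolist(), e[keep][order].tolist()):
            seqs.append(genome[c].sequence[a:b])
            if len(seqs) >= cap:
                return seqs
    return seqs
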