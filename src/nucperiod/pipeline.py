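"""End-to-end orchestration: synthetic or real mode, config-driven.

A run writes, under the output directory: per-profile TSVs, a JSON summary
(parameters, seeds, counts at every filter stage, period estimates, the
pathway-dinucleotide correlation matrix), a MANIFEST of completed stages
and a log file.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

try:
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - py<3.11
    import tomli as tomllib

import numpy as np
import pandas as pd

from . import fragments as frg
from . import io as nio
from . import periodicity as per
from . import profiles as prf
from . import sfs
from . import synthetic as syn
from .divergence import divergence_profile, polarize
from .genome import Genome

logger = logging.getLogger(__name__)

DEFAULT_PATHWAYS = [("G", "A"), ("C", "T"), ("A", "G")]
DEFAULT_DINUCS = ["AA", "TT", "GC"]


class ConfigError(ValueError):
    pass


DEFAULTS = {
    "chromatin": {
        "repeat_length": 180,
        "helical_period": 10.0,
        "rotational_amplitude": 0.3,
        "phase": 5.0,
        "linker_gc_boost": 0.3,
    },
    "evol": {
        "beta": 0.0,
        "theta": 0.02,
        "gamma": 0.0,
        "gamma_amplitude": 0.0,
        "sample_size": 34,
    },
    "synthetic": {
        "n_arrays": 200,
        "nucleosomes_per_array": 1,
        "jitter_sd": 0.0,
        "depth": 1,
        "length_min": 147,
        "length_max": 147,
    },
    "analysis": {
        "flank": 0,
        "trim": 5,
        "weighting": "per_n147",
        "n_permutations": 200,
        "period_range": [5.0, 20.0],
    },
}


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def validate_config(config: dict) -> dict:
    """Fill defaults and check required keys; errors name the missing key."""
    if "run" not in config or "mode" not in config.get("run", {}):
        raise ConfigError("missing required config key: run.mode")
    mode = config["run"]["mode"]
    if mode not in ("synthetic", "real"):
        raise ConfigError(f"run.mode must be 'synthetic' or 'real', got {mode!r}")
    merged = {"run": dict(config["run"])}
    for section, defaults in DEFAULTS.items():
        merged[section] = {**defaults, **config.get(section, {})}
    if mode == "real":
        inputs = config.get("inputs", {})
        for key in ("genome", "fragments", "annotation", "sites", "snps"):
            if key not in inputs:
                raise ConfigError(f"missing required config key: inputs.{key}")
        merged["inputs"] = dict(inputs)
    merged["run"].setdefault("seed", 0)
    return merged


def _chromatin_model(cfg: dict) -> syn.ChromatinModel:
    return syn.ChromatinModel(
        repeat_length=int(cfg["repeat_length"]),
        helical_period=float(cfg["helical_period"]),
        rotational_amplitude=float(cfg["rotational_amplitude"]),
        phase=float(cfg["phase"]),
        linker_gc_boost=float(cfg["linker_gc_boost"]),
    )


def _evol_params(cfg: dict, model: syn.ChromatinModel, seed: int) -> syn.EvolParams:
    return syn.EvolParams(
        beta=float(cfg["beta"]),
        theta=float(cfg["theta"]),
        gamma=float(cfg["gamma"]),
        gamma_amplitude=float(cfg["gamma_amplitude"]),
        sample_size=int(cfg["sample_size"]),
        helical_period=model.helical_period,
        phase=model.phase,
        seed=seed,
    )


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "MANIFEST"
        self.stages: list[str] = []

    def done(self, stage: str) -> None:
        self.stages.append(stage)
        self.path.write_text("\n".join(self.stages) + "\n")


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the configured analysis; returns the run summary dict.

    Any stage failure propagates after the MANIFEST of completed stages is
    written; partial outputs are retained.
    """
    config = validate_config(config)
    if seed is not None:
        config["run"]["seed"] = int(seed)
    seed = int(config["run"]["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    # no timestamps: reruns with the same seed must be byte-identical
    handler.setFormatter(logging.Formatter("%(name)s %(message)s"))
    root = logging.getLogger("nucperiod")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": seed, "mode": config["run"]["mode"], "config": _jsonable(config)}
    try:
        if config["run"]["mode"] == "synthetic":
            data = _synthesize(config, seed, outdir)
        else:
            data = _load_real(config)
        manifest.done("inputs")
        _analyze(config, data, outdir, summary, manifest)
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest.done("summary")
    finally:
        root.removeHandler(handler)
        handler.close()
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _synthesize(config: dict, seed: int, outdir: Path) -> dict:
    model = _chromatin_model(config["chromatin"])
    params = _evol_params(config["evol"], model, seed)
    s = config["synthetic"]
    genome, cores, annotation = syn.generate_genome(
        model, int(s["n_arrays"]), int(s["nucleosomes_per_array"]), seed=seed
    )
    alignment = syn.simulate_divergence(genome, cores, params)
    snps = syn.simulate_polymorphism(genome, cores, params)
    raw = syn.simulate_fragments(
        cores,
        jitter_sd=float(s["jitter_sd"]),
        length_range=range(int(s["length_min"]), int(s["length_max"]) + 1),
        depth=int(s["depth"]),
        seed=seed + 1,
        chrom_sizes=genome.lengths(),
    )
    genome.to_fasta(outdir / "genome.fa")
    syn.write_bed(cores, outdir / "true_cores.bed")
    syn.write_bed(annotation, outdir / "annotation.bed", name_column="region_class")
    syn.write_bed(raw, outdir / "fragments.bed")
    for chrom in genome:
        syn.write_alignment_fasta(alignment, chrom, outdir / f"alignment_{chrom}.fa")
    syn.write_snp_table(snps, outdir / "snps.tsv")
    chrom = next(iter(genome))
    sites = syn.alignment_to_site_table(alignment, chrom)
    return {
        "genome": genome,
        "fragments": raw,
        "annotation": annotation,
        "mask": None,
        "sites": sites,
        "snps": snps,
    }


def _load_real(config: dict) -> dict:
    inputs = config["inputs"]
    genome = Genome.from_fasta(inputs["genome"])
    fragments = nio.read_bed(inputs["fragments"])
    ann_path = str(inputs["annotation"])
    if ann_path.endswith((".gff", ".gff3")):
        annotation = nio.read_gff_annotation(ann_path)
    else:
        annotation = nio.read_bed(ann_path, class_column=True)
    mask = nio.read_bed(inputs["mask"]) if "mask" in inputs else None
    return {
        "genome": genome,
        "fragments": fragments,
        "annotation": annotation,
        "mask": mask,
        "sites": nio.read_site_table(inputs["sites"]),
        "snps": nio.read_snp_table(inputs["snps"]),
    }


def _analyze(config, data, outdir: Path, summary: dict, manifest: _Manifest) -> None:
    a = config["analysis"]
    genome: Genome = data["genome"]
    seed = summary["seed"]

    classified = frg.classify_fragments(
        data["fragments"], data["annotation"], flank=50, mask=data["mask"]
    )
    n147 = frg.select_n147(classified)
    track = frg.occupancy_track(classified, genome.lengths())
    frg.write_bedgraph(track, outdir / "occupancy.bedGraph")
    counts = {
        "fragments_total": int(len(classified)),
        "fragments_classified": int((classified["region_class"] != "excluded").sum()),
        "n147_total": int(len(n147)),
        "n147_intergenic": int((n147["region_class"] == "intergenic").sum()),
        "n147_intronic": int((n147["region_class"] == "intronic").sum()),
    }
    summary["counts"] = counts
    manifest.done("fragments")

    polarized = polarize(data["sites"], mode="standard")
    summary["counts"]["polarized_sites"] = int(polarized["polarized"].sum())
    manifest.done("polarize")

    flank = int(a["flank"])
    trim = int(a["trim"])
    weighting = a["weighting"]
    period_range = tuple(a["period_range"])
    div_profiles: dict = {}
    dpi_profiles: dict = {}
    dinuc_profiles: dict = {}
    periods: dict = {}
    for cls in ("intergenic", "intronic"):
        sub = n147[n147["region_class"] == cls].reset_index(drop=True)
        if not len(sub):
            continue
        div_profiles[cls] = {}
        dpi_profiles[cls] = {}
        dinuc_profiles[cls] = {}
        for dinuc in DEFAULT_DINUCS:
            p = prf.dinucleotide_profile(sub, genome, dinuc, flank=flank)
            sm = prf.smooth(p, "fine")
            p.write_tsv(outdir / f"dinuc_{cls}_{dinuc}.tsv", smoothed=sm)
            dinuc_profiles[cls][dinuc] = p
            periods[f"{cls}:dinuc:{dinuc}"] = _period_entry(
                p, period_range, seed, int(a["n_permutations"])
            )
        for pathway in DEFAULT_PATHWAYS:
            tag = f"{pathway[0]}{pathway[1]}"
            p = divergence_profile(
                polarized, sub, genome.lengths(), pathway,
                weighting=weighting, trim=trim, flank=flank,
            )
            sm = prf.smooth(p, "fine")
            p.write_tsv(outdir / f"div_{cls}_{tag}.tsv", smoothed=sm)
            div_profiles[cls][pathway] = p
            periods[f"{cls}:div:{tag}"] = _period_entry(
                p, period_range, seed, int(a["n_permutations"])
            )
            d = sfs.delta_pi_profile(
                data["snps"], sub, genome.lengths(), pathway,
                weighting=weighting, trim=trim, flank=flank,
            )
            sm = prf.smooth(d, "fine")
            d.write_tsv(outdir / f"dpi_{cls}_{tag}.tsv", smoothed=sm)
            dpi_profiles[cls][pathway] = d
    manifest.done("profiles")

    summary["periods"] = periods
    summary["significant_periodicity"] = {
        k: bool(v["significant"]) for k, v in periods.items()
    }
    summary["any_significant_periodicity"] = any(
        v["significant"] for v in periods.values()
    )

    table1 = per.table1_matrix(div_profiles, dpi_profiles, dinuc_profiles)
    table1.to_csv(outdir / "table1_correlations.tsv", sep="\t")
    summary["table1"] = {
        row: {col: (None if pd.isna(v) else float(v)) for col, v in table1.loc[row].items()}
        for row in table1.index
    }
    manifest.done("correlations")

    # genome-wide per-pathway summary (Table-S4-style layout)
    rows = []
    for pathway in DEFAULT_PATHWAYS:
        tag = f"{pathway[0]}->{pathway[0]}{pathway[1]}"
        sel = data["snps"][
            (data["snps"]["ancestral"] == pathway[0])
            & (data["snps"]["derived"] == pathway[1])
        ]
        if len(sel):
            dpi, se, s_count = sfs.aggregate_delta_pi(sel, n_min=4)
            pi_mean = float(np.mean(sfs.pi_per_snp(sel["i"].to_numpy(), sel["n"].to_numpy())))
        else:
            dpi = se = pi_mean = np.nan
            s_count = 0
        rows.append({"pathway": tag, "snps": s_count, "pi_per_snp": pi_mean,
                     "delta_pi": dpi, "se": se})
    pd.DataFrame(rows).to_csv(outdir / "pathway_summary.tsv", sep="\t", index=False)
    manifest.done("pathway_summary")


def _period_entry(profile, period_range, seed, n_permutations) -> dict:
    try:
        obs, null = per.permutation_null(
            profile, period_range=period_range, detrend="linear",
            n_permutations=n_permutations, seed=seed,
        )
        est = per.estimate_period(profile, period_range, detrend="linear")
        # a profile is flagged only when it beats every permutation: with many
        # profiles per run, the per-profile 95th percentile would false-flag
        # under the global null
        return {
            "period": est.period,
            "prominence": obs,
            "null_p95": float(np.percentile(null, 95)),
            "null_max": float(null.max()),
            "significant": bool(obs > null.max()),
        }
    except ValueError as exc:
        return {"period": None, "prominence": None, "null_p95": None,
                "significant": False, "error": str(exc)}
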