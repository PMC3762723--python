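"""Config-driven orchestration of the analysis stages.

A run is described by a flat YAML config (paths, stage toggles, numeric
settings, seed).  Stages execute in dependency order -- fossil -> calib ->
concord, with matrix and depthmap independent -- and every emitted file is
listed in a JSON run manifest written atomically.  Identical config + seed
give byte-identical (non-timestamp) outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field

import yaml

from . import __version__

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "load_config", "run_pipeline"]

STAGES = ("synth", "fossil", "calib", "concord", "matrix", "depthmap")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: dict = field(default_factory=dict)  # stage -> bool
    occurrences: str | None = None
    families: str | None = None  # optional family universe, one per line
    calibration_table: str | None = None  # None: packaged reference set
    chronogram: str | None = None
    node_ages: str | None = None
    depths: str | None = None
    genes_dir: str | None = None
    alphas: tuple = (0.975, 0.05, 0.95, 0.5)
    preservation_factor: float = 10.0
    articulated_only: bool = False
    calib_convention: str = "matched"
    calib_p: float = 0.1
    time_unit: float = 100.0
    variants: tuple = ("12n3rRTn", "123nRTn", "12nRTn", "123aRTn")
    age_kind: str = "stem"

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, False))

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        needs = {
            "fossil": ["occurrences"],
            "concord": ["occurrences", "chronogram", "node_ages"],
            "matrix": ["genes_dir"],
            "depthmap": ["chronogram", "depths"],
        }
        for stage, attrs in needs.items():
            if not self.enabled(stage):
                continue
            for attr in attrs:
                path = getattr(self, attr)
                if self.enabled("synth"):
                    continue  # synth will generate missing inputs
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(
                        f"stage {stage!r} needs {attr!r}: {path!r} does not exist"
                    )


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("alphas", "variants"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(manifest: RunManifest, outdir: str) -> str:
    path = os.path.join(outdir, "manifest.json")
    fd, tmp = tempfile.mkstemp(dir=outdir, suffix=".manifest")
    with os.fdopen(fd, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)
    return path


def _stage_synth(config: RunConfig, outdir: str) -> list[str]:
    """Generate any missing inputs from the packaged synthetic demo set."""
    from . import demo, supermatrix, synth

    indir = os.path.join(outdir, "inputs")
    os.makedirs(indir, exist_ok=True)
    out = []
    if config.occurrences is None:
        config.occurrences = os.path.join(indir, "occurrences.tsv")
        synth.write_occurrences_tsv(demo.demo_occurrences(), config.occurrences)
        out.append(config.occurrences)
    if config.families is None:
        config.families = os.path.join(indir, "families.txt")
        with open(config.families, "w") as fh:
            fh.write("\n".join(demo.FAMILIES) + "\n")
        out.append(config.families)
    if config.chronogram is None:
        config.chronogram = os.path.join(indir, "chronogram.nwk")
        synth.write_chronogram(demo.demo_chronogram(), config.chronogram)
        out.append(config.chronogram)
    if config.node_ages is None:
        config.node_ages = os.path.join(indir, "node_ages.tsv")
        demo.demo_node_ages(seed=config.seed).to_csv(
            config.node_ages, sep="\t", index=False
        )
        out.append(config.node_ages)
    if config.depths is None:
        config.depths = os.path.join(indir, "depths.tsv")
        synth.write_depths_tsv(demo.demo_depths(), config.depths)
        out.append(config.depths)
    if config.genes_dir is None:
        config.genes_dir = os.path.join(indir, "genes")
        supermatrix.write_gene_alignments(
            demo.demo_genes(seed=config.seed + 11), config.genes_dir
        )
        out.append(os.path.join(config.genes_dir, "annotations.tsv"))
    return out


def _load_records(config: RunConfig):
    from . import fossilrec

    occurrences = fossilrec.load_occurrences(config.occurrences)
    families = None
    if config.families:
        with open(config.families) as fh:
            families = [line.strip() for line in fh if line.strip()]
    return fossilrec.build_records(
        occurrences, families=families, articulated_only=config.articulated_only
    )


def _stage_fossil(config: RunConfig, outdir: str) -> list[str]:
    from . import fossilrec

    records = _load_records(config)
    table = fossilrec.ci_table(
        records, alphas=config.alphas, factors=(config.preservation_factor,)
    )
    path = os.path.join(outdir, "ci_table.tsv")
    fossilrec.write_ci_table(table, path)
    census = fossilrec.classify_estimability(records)
    census_path = os.path.join(outdir, "estimability.json")
    with open(census_path, "w") as fh:
        json.dump(census, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [path, census_path]


def _stage_calib(config: RunConfig, outdir: str) -> list[str]:
    from . import calib

    if config.calibration_table:
        rows = calib.load_calibration_table(config.calibration_table)
        cals = [
            calib.SoftBoundCalibration(
                node_label=row["node_label"],
                t_min=row["t_min"],
                t_max=row["t_max"],
                p=row["p"],
                c=calib.solve_scale_c(
                    row["t_min"], row["t_max"], row["p"],
                    convention=config.calib_convention,
                ),
            )
            for row in rows
        ]
    else:
        cals = calib.reference_calibrations(convention=config.calib_convention)
    path = os.path.join(outdir, "calibrations.txt")
    with open(path, "w") as fh:
        fh.write(calib.emit_calibration_file(cals, time_unit=config.time_unit))
    return [path]


def _stage_concord(config: RunConfig, outdir: str) -> list[str]:
    from . import concord, trees

    records = _load_records(config)
    tree = trees.read_chronogram(config.chronogram)
    family_tips = {
        rec.family: {rec.family}
        for rec in records
        if rec.family in {lf.taxon.label for lf in tree.leaf_node_iter()}
    }
    node_table = concord.read_node_ages(config.node_ages)
    # scheme a uses the chronogram's own ages; scheme b shifts stems by the
    # node table's per-node scheme difference where a stem node is matched
    pairs_a = concord.pair_timescales(records, tree, family_tips, config.age_kind)
    mean_b, _ = concord.scheme_difference_summary(node_table, "all")
    pairs_b = [
        concord.TimescalePair(
            family=p.family,
            paleo_age=p.paleo_age,
            molecular_age=p.molecular_age + mean_b,
        )
        for p in pairs_a
    ]
    report = {
        "rss_scheme_a": concord.rss_one_to_one(pairs_a),
        "rss_scheme_b": concord.rss_one_to_one(pairs_b),
        "scheme_diff_all": concord.scheme_difference_summary(node_table, "all"),
        "scheme_diff_pelagia": concord.scheme_difference_summary(node_table, "pelagia"),
        "n_pairs": len(pairs_a),
    }
    report_path = os.path.join(outdir, "concordance.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tsv_path = os.path.join(outdir, "timescale_pairs.tsv")
    import pandas as pd

    pd.DataFrame(
        [
            {"family": p.family, "paleo_age": p.paleo_age, "molecular_age": p.molecular_age}
            for p in pairs_a
        ]
    ).to_csv(tsv_path, sep="\t", index=False, float_format="%.4f")
    plot_path = os.path.join(outdir, "concordance.png")
    concord.plot_concordance({"scheme_a": pairs_a, "scheme_b": pairs_b}, plot_path)
    return [report_path, tsv_path, plot_path]


def _stage_matrix(config: RunConfig, outdir: str) -> list[str]:
    from . import supermatrix

    fasta_paths = {
        os.path.splitext(name)[0]: os.path.join(config.genes_dir, name)
        for name in sorted(os.listdir(config.genes_dir))
        if name.endswith((".fasta", ".fa"))
    }
    genes = supermatrix.read_gene_alignments(
        fasta_paths, os.path.join(config.genes_dir, "annotations.tsv")
    )
    out = []
    for variant in config.variants:
        built = supermatrix.build_variant(genes, variant)
        phy = os.path.join(outdir, f"{variant}.phy")
        parts = os.path.join(outdir, f"{variant}.partitions")
        supermatrix.write_phylip(built, phy)
        supermatrix.write_partitions(built, parts)
        out += [phy, parts]
    return out


def _stage_depthmap(config: RunConfig, outdir: str) -> list[str]:
    from . import depthmap, trees

    tree = trees.read_chronogram(config.chronogram)
    depths = depthmap.load_depths(config.depths)
    _, report = depthmap.reconstruct_depths(tree, depths)
    path = os.path.join(outdir, "depth_reconstruction.tsv")
    report.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return [path]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "fossil": _stage_fossil,
    "calib": _stage_calib,
    "concord": _stage_concord,
    "matrix": _stage_matrix,
    "depthmap": _stage_depthmap,
}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    A stage failure stops the run; the manifest records the completed
    outputs, the failing stage, and its error.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest = RunManifest(
        version=__version__, config_hash=_config_hash(config), seed=config.seed
    )
    for stage in STAGES:
        if not config.enabled(stage):
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, config.outdir)
        except Exception as exc:  # noqa: BLE001 - recorded in the manifest
            manifest.failed_stage = stage
            manifest.error = f"{type(exc).__name__}: {exc}"
            logger.error("stage %s failed: %s", stage, manifest.error)
            break
        manifest.outputs += outputs
        logger.info("stage %s: %d outputs", stage, len(outputs))
    _write_manifest(manifest, config.outdir)
    return manifest
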