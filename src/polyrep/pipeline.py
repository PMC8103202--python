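"""End-to-end orchestration: simulate -> classify -> annotate -> group -> stats.

Each stage reads and writes plain-text artifacts (FASTA/TSV/JSON) in the
output directory, logs one line with record counts in/out, and is
re-runnable in isolation through the CLI.  A run manifest lists every
artifact with its SHA-256 checksum; a rerun with the same configuration and
seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from polyrep import annotate as ann_mod
from polyrep import clones as clone_mod
from polyrep import reactivity as react_mod
from polyrep import simulate as sim_mod
from polyrep import stats as stats_mod
from polyrep.germline import HEAVY, KAPPA, load_default_germline

log = logging.getLogger("polyrep")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    outdir: str = "polyrep_run"
    seed: int = 0
    sjs_size: int = 56
    b6_size: int = 62
    threshold_policy: str = "adaptive"
    threshold_k: float = 3.0
    fixed_cutoff: float | None = None
    stages: tuple[str, ...] = ("simulate", "reactivity", "annotate", "clones", "stats")
    input_dir: str | None = None  # read an existing library instead of simulating

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(paths: dict[str, Path]) -> list[dict]:
    """Schema checks on input artifacts; returns an itemized failure report.

    TSVs are checked for their required columns, FASTA records for alphabet
    (ambiguity codes warn rather than fail).  Report-only: never raises.
    """
    from Bio import SeqIO

    failures: list[dict] = []
    schemas = {
        "meta_od": ["id", "strain", "age_weeks", "isotype", "subclass",
                    "autoreactive_flag", *sim_mod.ANTIGENS],
        "blanks": ["well", "od"],
    }
    for key, required in schemas.items():
        path = paths.get(key)
        if path is None:
            continue
        if not Path(path).exists():
            failures.append({"file": str(path), "error": "missing file"})
            continue
        cols = pd.read_csv(path, sep="\t", nrows=0).columns
        for col in required:
            if col not in cols:
                failures.append({"file": str(path), "error": f"missing column {col!r}"})
    for key in ("heavy_fasta", "kappa_fasta"):
        path = paths.get(key)
        if path is None:
            continue
        if not Path(path).exists():
            failures.append({"file": str(path), "error": "missing file"})
            continue
        for rec in SeqIO.parse(str(path), "fasta"):
            letters = set(str(rec.seq).upper())
            if not letters <= set("ACGTNRYSWKMBDHV"):
                failures.append({"file": str(path), "record": rec.id,
                                 "error": "non-nucleotide characters"})
            elif not letters <= set("ACGT"):
                failures.append({"file": str(path), "record": rec.id,
                                 "warning": "ambiguity codes present"})
    return failures


def run(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    artifacts: list[Path] = [outdir / "config.yaml"]
    reference = load_default_germline()

    # --- simulate / load -----------------------------------------------------
    if "simulate" in config.stages:
        library = sim_mod.simulate_study(config.seed, sjs_size=config.sjs_size,
                                         b6_size=config.b6_size, reference=reference)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
        paths = sim_mod.write_library(library, outdir / "library", rng)
        artifacts += list(paths.values())
        log.info("simulate: %d records -> %s", len(library), outdir / "library")
    elif config.input_dir:
        paths = {k: Path(config.input_dir) / v for k, v in (
            ("heavy_fasta", "heavy.fasta"), ("kappa_fasta", "kappa.fasta"),
            ("meta_od", "meta_od.tsv"), ("blanks", "blanks.tsv"))}
    else:
        raise ValueError("no simulate stage and no input_dir given")

    report = validate_inputs(paths)
    hard = [f for f in report if "error" in f]
    if hard:
        raise ValueError(f"input validation failed: {hard}")

    meta_od = pd.read_csv(paths["meta_od"], sep="\t", dtype={"id": str},
                          keep_default_na=False)
    blanks = pd.read_csv(paths["blanks"], sep="\t")

    classified = None
    if "reactivity" in config.stages:
        classified, prov = react_mod.classify_od_table(
            meta_od, blanks, policy=config.threshold_policy,
            k=config.threshold_k, cutoff=config.fixed_cutoff)
        classified.to_csv(outdir / "classified.tsv", sep="\t", index=False)
        heat = react_mod.build_heatmap_matrix(meta_od, background=prov.cutoff)
        heat.to_csv(outdir / "heatmap.tsv", sep="\t")
        (outdir / "threshold.json").write_text(json.dumps(prov.as_dict(), indent=2))
        artifacts += [outdir / "classified.tsv", outdir / "heatmap.tsv",
                      outdir / "threshold.json"]
        log.info("reactivity: %d records classified (threshold %.4f)",
                 len(classified), prov.cutoff)

    annotations = None
    if "annotate" in config.stages:
        seqs = ann_mod.read_chain_fasta(paths["heavy_fasta"], paths["kappa_fasta"])
        meta_cols = meta_od[["id", "strain", "age_weeks", "isotype", "subclass"]]
        annotations = ann_mod.annotate_library(seqs, reference, metadata=meta_cols)
        annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        artifacts.append(outdir / "annotations.tsv")
        log.info("annotate: %d chains in, %d records out", len(seqs), len(annotations))

    if "clones" in config.stages:
        if annotations is None:
            raise ValueError("clones stage requires the annotate stage")
        productive = annotations[
            annotations["heavy_productive"].astype(bool)
            & annotations["kappa_productive"].astype(bool)
        ]
        clonesets, membership = clone_mod.group_clones(productive)
        membership.to_csv(outdir / "clone_sets.tsv", sep="\t", index=False)
        denoms = {
            key: len(grp) for key, grp in
            productive.groupby(["strain", "age_weeks", "isotype"])
        }
        oligo = clone_mod.oligoclonality(
            clonesets, productive[["id", "strain", "age_weeks", "isotype"]], denoms)
        oligo.to_json(outdir / "oligoclonality.json", orient="records", indent=2)
        artifacts += [outdir / "clone_sets.tsv", outdir / "oligoclonality.json"]
        log.info("clones: %d records in, %d clone sets", len(productive), len(clonesets))

    if "stats" in config.stages:
        if classified is None:
            raise ValueError("stats stage requires the reactivity stage")
        statsdir = outdir / "stats"
        statsdir.mkdir(exist_ok=True)
        auto = classified.copy()
        auto["autoreactivity"] = np.where(
            auto["autoreactive_flag"].astype(int) == 1, "autoreactive", "non-autoreactive")
        fig1 = stats_mod.tabulate(auto, category_col="autoreactivity",
                                  categories=("autoreactive", "non-autoreactive"))
        fig1.to_csv(statsdir / "fig1_autoreactive_freq.tsv", sep="\t", index=False)
        ro52 = classified.copy()
        ro52["ro52_reactivity"] = np.where(ro52["anti_ro52"], "anti-Ro52", "other")
        fig2 = stats_mod.tabulate(ro52, category_col="ro52_reactivity",
                                  categories=("anti-Ro52", "other"))
        fig2.to_csv(statsdir / "fig2_ro52_freq.tsv", sep="\t", index=False)
        fig3 = stats_mod.tabulate(classified)
        fig3.to_csv(statsdir / "fig3_category_freq.tsv", sep="\t", index=False)
        tests = stats_mod.category_chi_square_by_strain(fig3)
        artifacts += [statsdir / "fig1_autoreactive_freq.tsv",
                      statsdir / "fig2_ro52_freq.tsv",
                      statsdir / "fig3_category_freq.tsv"]
        if annotations is not None:
            poly_ids = set(classified.loc[classified["category"] == "polyreactive", "id"])
            poly_igg = annotations[
                annotations["id"].isin(poly_ids) & annotations["isotype"].eq("IgG")]
            fig5a = stats_mod.subclass_distribution(poly_igg)
            fig5a.to_csv(statsdir / "fig5a_subclass.tsv", sep="\t", index=False)
            fig5b = stats_mod.summarize_cdr3(poly_igg)
            fig5b.to_csv(statsdir / "fig5b_cdr3.tsv", sep="\t", index=False)
            fig5c = poly_igg[["id", "strain", "age_weeks", "heavy_aa_replacements"]]
            fig5c.to_csv(statsdir / "fig5c_vh_replacements.tsv", sep="\t", index=False)
            groups = {
                strain: pd.to_numeric(grp["heavy_aa_replacements"],
                                      errors="coerce").dropna()
                for strain, grp in poly_igg.groupby("strain")
            }
            if len(groups) == 2:
                a, b = groups.values()
                if len(a) >= 2 and len(b) >= 2:
                    res = stats_mod.t_test_mutations(a, b)
                    tests.append({"comparison": "vh-replacements-between-strains",
                                  "strains": list(groups), **res.as_dict()})
            artifacts += [statsdir / "fig5a_subclass.tsv", statsdir / "fig5b_cdr3.tsv",
                          statsdir / "fig5c_vh_replacements.tsv"]
        (statsdir / "tests.json").write_text(json.dumps(tests, indent=2))
        artifacts.append(statsdir / "tests.json")
        log.info("stats: %d test results", len(tests))

    manifest = {
        "seed": config.seed,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
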