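"""End-to-end orchestration: simulate (or load) -> classify -> prune ->
single-variant association -> clumping -> sliding-window kernel tests ->
region merging -> mutation screen, with TSV/BED/JSON artifacts and a run
manifest.

All tabular artifacts are TSV with a single header line; BED exports are
0-based half-open (converted from the package's 1-based inclusive
intervals). Identical config and seed reproduce byte-identical numeric
outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import ADJUST_METHODS, SingleVariantAssociation, test_normality
from .kernel import SlidingWindowKernelTest
from .prune import ClumpParams, PruneParams, clump, vif_prune
from .screen import ScreenCriteria, filter_candidates, screen_report
from .simulate import (
    TailDesign,
    annotate_variants_synthetic,
    default_study_config,
    select_tails,
    simulate_study_cohort,
    write_vcf,
)
from .variants import (
    COMMON_MAF_THRESHOLD,
    GenotypeMatrix,
    VariantRecord,
    read_vcf,
    summarize_variants,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report"]


class PipelineError(RuntimeError):
    """A stage failed; the failing stage is named in the message."""


@dataclass
class RunConfig:
    """Configuration of a full run.

    Exactly one of ``simulate`` (True, or a seed-driven simulation block)
    or ``inputs`` (paths to a VCF, a phenotype TSV with columns
    id/fxi_pct/age/sex, and optionally an annotation TSV) must be set.
    """

    outdir: str
    seed: int = 0
    simulate: bool = True
    inputs: dict | None = None  # {"vcf": ..., "phenotypes": ..., "annotations": ...}
    maf_threshold: float = COMMON_MAF_THRESHOLD
    prune: PruneParams = field(default_factory=PruneParams)
    clump_params: ClumpParams = field(default_factory=ClumpParams)
    adjust_methods: tuple[str, ...] = tuple(ADJUST_METHODS)
    window_bp: int = 2000
    weight_beta: tuple[float, float] = (1.0, 25.0)
    n_permutations: int = 1000
    alpha: float = 0.05
    screen: ScreenCriteria = field(default_factory=ScreenCriteria)
    tail_design: TailDesign = field(default_factory=TailDesign)

    def __post_init__(self) -> None:
        if bool(self.simulate) == bool(self.inputs):
            raise ValueError("exactly one of simulate / inputs must be configured")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, ctor in (
            ("prune", PruneParams),
            ("clump_params", ClumpParams),
            ("screen", ScreenCriteria),
            ("tail_design", TailDesign),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = ctor(**raw[key])
        if "adjust_methods" in raw:
            raw["adjust_methods"] = tuple(raw["adjust_methods"])
        if "weight_beta" in raw:
            raw["weight_beta"] = tuple(raw["weight_beta"])
        return cls(**raw)


def _load_annotations(path: str, records: list[VariantRecord]) -> list[VariantRecord]:
    """Merge an annotation TSV (chrom, pos, ref, alt, dbsnp_id, hgvs_c, gene,
    feature_location, exon_distance_bp, plus ``af_<panel>`` columns) onto
    VCF-derived records."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ann_idx = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): r
        for r in ann.itertuples()
    }
    panel_cols = [c for c in ann.columns if c.startswith("af_")]
    out = []
    for v in records:
        row = ann_idx.get((v.chrom, v.pos, v.ref, v.alt))
        if row is None:
            out.append(v)
            continue
        afs = {
            c[3:]: float(getattr(row, c))
            for c in panel_cols
            if pd.notna(getattr(row, c))
        }
        dist = getattr(row, "exon_distance_bp", None)
        out.append(
            VariantRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                dbsnp_id=None if pd.isna(row.dbsnp_id) else str(row.dbsnp_id),
                is_indel=v.is_indel,
                hgvs_c=None if pd.isna(getattr(row, "hgvs_c", None)) else str(row.hgvs_c),
                gene=None if pd.isna(getattr(row, "gene", None)) else str(row.gene),
                feature_location=None
                if pd.isna(row.feature_location)
                else str(row.feature_location),
                exon_distance_bp=None if dist is None or pd.isna(dist) else int(dist),
                ref_panel_afs=afs,
            )
        )
    return out


def _regions_to_bed(regions, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# BED 0-based half-open; converted from 1-based inclusive\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tn_sets={r.n_sets}\n")


_STAGE_DEPS = {
    "data": set(),
    "classify": {"data"},
    "prune": {"data", "classify"},
    "single_assoc": {"data", "classify", "prune"},
    "clump": {"data", "classify", "prune", "single_assoc"},
    "set_assoc": {"data", "classify", "prune"},
    "screen": {"data", "classify"},
}


def run_pipeline(config: RunConfig, stages: set[str] | None = None) -> dict:
    """Execute the pipeline and write artifacts under ``config.outdir``.

    ``stages`` restricts execution to the named stages plus their
    prerequisites (default: all). Returns the manifest dict (also written
    to ``manifest.json``).
    """
    if stages is None:
        wanted = set(_STAGE_DEPS)
    else:
        unknown = stages - set(_STAGE_DEPS)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        wanted = set(stages)
        for s in list(stages):
            wanted |= _STAGE_DEPS[s]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "maf_threshold": config.maf_threshold,
            "prune": vars(config.prune) | {},
            "clump": vars(config.clump_params) | {},
            "adjust_methods": list(config.adjust_methods),
            "window_bp": config.window_bp,
            "weight_beta": list(config.weight_beta),
            "n_permutations": config.n_permutations,
            "alpha": config.alpha,
            "screen": {
                "rare_af_threshold": config.screen.rare_af_threshold,
                "intronic_distance_max_bp": config.screen.intronic_distance_max_bp,
                "unannotated_sample_maf_threshold": config.screen.unannotated_sample_maf_threshold,
            },
        },
        "stages": {},
    }

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **counts,
            }

        return done

    # ---- stage: data -------------------------------------------------
    done = stage("data")
    try:
        if config.simulate:
            sim = default_study_config(seed=config.seed)
            genotypes, variants, phenotypes, discovery = simulate_study_cohort(
                sim, design=config.tail_design
            )
            target_mafs = np.concatenate([np.asarray(l.mafs) for l in sim.loci])
            variants = annotate_variants_synthetic(variants, target_mafs, seed=config.seed)
            write_vcf(genotypes, variants, str(outdir / "genotypes.vcf"))
            phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
            pd.DataFrame({"id": discovery}).to_csv(
                outdir / "discovery_sample.tsv", sep="\t", index=False
            )
            loci = [
                (l.name, l.chrom, l.start_bp, l.end_bp) for l in sim.loci
            ]
        else:
            genotypes, variants, n_multi = read_vcf(config.inputs["vcf"])
            phenotypes = pd.read_csv(config.inputs["phenotypes"], sep="\t")
            if "annotations" in config.inputs and config.inputs["annotations"]:
                variants = _load_annotations(config.inputs["annotations"], variants)
            genotypes = genotypes.subset_individuals(list(phenotypes["id"]))
            chroms = sorted({v.chrom for v in variants})
            loci = [
                (
                    c,
                    c,
                    min(v.pos for v in variants if v.chrom == c),
                    max(v.pos for v in variants if v.chrom == c),
                )
                for c in chroms
            ]
        done(n_individuals=genotypes.n_individuals, n_variants=genotypes.n_variants)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'data' failed: {exc}") from exc

    y = phenotypes["fxi_pct"].to_numpy(dtype=float)
    covariates = phenotypes[["age", "sex"]].to_numpy(dtype=float)
    positions = np.array([v.pos for v in variants])
    chrom_arr = [v.chrom for v in variants]
    vids = [v.variant_id for v in variants]

    # ---- stage: classify ---------------------------------------------
    done = stage("classify")
    try:
        norm = test_normality(y)
        mafs = genotypes.mafs()
        poly = np.array(
            [
                np.ptp(genotypes.dosages[~np.isnan(genotypes.dosages[:, j]), j]) > 0
                for j in range(genotypes.n_variants)
            ]
        )
        freq_class = np.where(mafs >= config.maf_threshold, "common", "low_frequency")
        class_df = pd.DataFrame(
            {
                "variant_id": vids,
                "chrom": chrom_arr,
                "position": positions,
                "maf": mafs,
                "polymorphic": poly,
                "frequency_class": freq_class,
            }
        )
        class_df.to_csv(outdir / "variant_classes.tsv", sep="\t", index=False)
        summary = summarize_variants(variants, loci)
        summary.to_csv(outdir / "variant_summary.tsv", sep="\t", index=False)
        done(
            n_common=int((poly & (freq_class == "common")).sum()),
            n_low_frequency=int((poly & (freq_class == "low_frequency")).sum()),
            n_monomorphic=int((~poly).sum()),
            shapiro_W=norm.W,
            shapiro_p=norm.p,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'classify' failed: {exc}") from exc

    # ---- stage: prune ------------------------------------------------
    if "prune" in wanted:
        done = stage("prune")
        try:
            retained: dict[str, list[str]] = {}
            logs = []
            for cls in ("common", "low_frequency"):
                ids = [
                    vids[j]
                    for j in np.argsort(np.arange(len(vids)))
                    if freq_class[j] == cls and poly[j]
                ]
                kept, log = vif_prune(genotypes, order=ids, params=config.prune)
                retained[cls] = kept
                log.insert(0, "frequency_class", cls)
                logs.append(log)
            pd.concat(logs, ignore_index=True).to_csv(
                outdir / "prune_log.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                {
                    "variant_id": retained["common"] + retained["low_frequency"],
                    "frequency_class": ["common"] * len(retained["common"])
                    + ["low_frequency"] * len(retained["low_frequency"]),
                }
            ).to_csv(outdir / "pruned_variants.tsv", sep="\t", index=False)
            done(
                n_common_retained=len(retained["common"]),
                n_low_frequency_retained=len(retained["low_frequency"]),
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'prune' failed: {exc}") from exc

    # ---- stage: single-variant association ---------------------------
    if "single_assoc" in wanted:
        done = stage("single_assoc")
        try:
            common_ids = retained["common"]
            sub = genotypes.subset_variants(common_ids)
            est = SingleVariantAssociation(methods=config.adjust_methods)
            est.fit(sub.dosages, y, covariates=covariates, variant_ids=common_ids)
            assoc = est.to_table([v for v in variants if v.variant_id in set(common_ids)])
            pos_map = dict(zip(vids, positions))
            assoc.insert(2, "position", [pos_map[v] for v in assoc["variant_id"]])
            assoc.to_csv(outdir / "single_association.tsv", sep="\t", index=False)
            done(n_tested=len(assoc), n_skipped=len(est.skipped_))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'single_assoc' failed: {exc}") from exc

    # ---- stage: clump ------------------------------------------------
    if "clump" in wanted:
        done = stage("clump")
        try:
            clumps = clump(
                assoc[["variant_id", "position", "p"]],
                genotypes,
                params=config.clump_params,
            )
            rows = [
                {
                    "index_variant": c.index_variant,
                    "index_p": c.index_p,
                    "n_members": c.size,
                    "members": ",".join(c.members) or ".",
                }
                for c in clumps
            ]
            pd.DataFrame(
                rows, columns=["index_variant", "index_p", "n_members", "members"]
            ).to_csv(outdir / "clumps.tsv", sep="\t", index=False)
            done(n_clumps=len(clumps))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'clump' failed: {exc}") from exc

    # ---- stage: set association --------------------------------------
    if "set_assoc" in wanted:
        done = stage("set_assoc")
        try:
            low_ids = retained["low_frequency"]
            low_idx = [vids.index(v) for v in low_ids]
            sub = genotypes.subset_variants(low_ids)
            kt = SlidingWindowKernelTest(
                maf_threshold=config.maf_threshold,
                width_bp=config.window_bp,
                weight_beta_a=config.weight_beta[0],
                weight_beta_b=config.weight_beta[1],
                B=config.n_permutations,
                alpha=config.alpha,
                random_state=config.seed,
            )
            kt.fit(
                sub.dosages,
                y,
                positions=positions[low_idx],
                chroms=[chrom_arr[j] for j in low_idx],
                covariates=covariates,
                variant_ids=low_ids,
            )
            kt.results_.to_csv(outdir / "variant_sets.tsv", sep="\t", index=False)
            _regions_to_bed(kt.regions_nominal_, outdir / "regions_nominal.bed")
            _regions_to_bed(kt.regions_fwer_, outdir / "regions_fwer.bed")
            done(
                n_sets=len(kt.sets_),
                n_nominal=int(sum(s.p < config.alpha for s in kt.sets_ if s.p is not None)),
                n_fwer_significant=int(sum(bool(s.significant_fwer) for s in kt.sets_)),
                n_regions_nominal=len(kt.regions_nominal_),
                n_regions_fwer=len(kt.regions_fwer_),
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'set_assoc' failed: {exc}") from exc

    # ---- stage: screen -----------------------------------------------
    if "screen" in wanted:
        done = stage("screen")
        try:
            maf_map = dict(zip(vids, mafs))
            results = filter_candidates(variants, maf_map, criteria=config.screen)
            report = screen_report(results)
            report.to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
            done(n_screened=len(results), n_candidates=int(report["candidate"].sum()))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'screen' failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_report(outdir: str) -> str:
    """Human-readable run summary assembled from the stage artifacts.

    Missing artifacts are listed as absent, not fatal; no number is
    recomputed here.
    """
    out = Path(outdir)
    lines = ["# Run report", ""]

    def section(title: str, fname: str, render) -> None:
        lines.append(f"## {title}")
        path = out / fname
        if not path.exists():
            lines.append(f"[absent: {fname}]")
            lines.append("")
            return
        render(path)
        lines.append("")

    def tsv_head(path: Path, n: int = 15) -> None:
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            lines.append("no rows (no significant findings)")
        else:
            lines.append(df.head(n).to_string(index=False))

    def tsv_head_sorted(path: Path) -> None:
        df = pd.read_csv(path, sep="\t").sort_values("p")
        lines.append(df.head(15).to_string(index=False))

    section("Variant summary", "variant_summary.tsv", tsv_head)
    section(
        "Single-variant association (top rows by p)",
        "single_association.tsv",
        tsv_head_sorted,
    )
    section("Independent signals (clumps)", "clumps.tsv", tsv_head)
    section(
        "Low-frequency variant sets (top rows by p)",
        "variant_sets.tsv",
        lambda p: lines.append(
            pd.read_csv(p, sep="\t").sort_values("p").head(15).to_string(index=False)
        ),
    )

    def bed(path: Path) -> None:
        text = path.read_text().strip().splitlines()
        body = [l for l in text if not l.startswith("#")]
        lines.extend(body if body else ["no regions (no significant findings)"])

    section("Merged regions, nominal tier", "regions_nominal.bed", bed)
    section("Merged regions, FWER tier", "regions_fwer.bed", bed)

    def screen_sec(path: Path) -> None:
        df = pd.read_csv(path, sep="\t")
        cands = df[df["candidate"]]
        lines.append(f"{len(df)} variants screened, {len(cands)} candidates")
        if not cands.empty:
            lines.append(cands.head(15).to_string(index=False))

    section("Mutation screen", "screen_results.tsv", screen_sec)

    manifest = out / "manifest.json"
    lines.append("## Manifest")
    if manifest.exists():
        lines.append(manifest.read_text())
    else:
        lines.append("[absent: manifest.json]")
    return "\n".join(lines)
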