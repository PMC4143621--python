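"""End-to-end null-scan experiments: simulate, scan, summarize, report.

One run fixes a trait mode — ``dichotomized_polygenic`` (polygenic trait cut
at the founder quantile) or ``complete_null`` (random affection) — then
generates pedigrees and gene-dropped genotypes, estimates founder MAFs,
scans every marker with two-point parametric linkage per replicate, and
summarizes false-positive counts across replicates.  Everything derives
from (config, seed); per-replicate randomness depends only on
(seed, replicate index).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import allele_freq, genotypes, phenotypes, synthetic_data
from .evaluation import (
    ExperimentSummary,
    ReplicateSummary,
    Thresholds,
    summarize_experiment,
    summarize_replicate,
)
from .linkage import DEFAULT_THETA_GRID, TraitModel, TwoPointScan, write_lod_table
from .pedigree import detect_loops, write_pedigrees
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)

TRAIT_MODES = ("dichotomized_polygenic", "complete_null")
THETA_POLICIES = ("zero_only", "grid_max")


@dataclass
class ExperimentSpec:
    trait_mode: str = "complete_null"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    model: TraitModel = field(default_factory=TraitModel)
    thresholds: Thresholds = field(default_factory=Thresholds)
    theta_policy: str = "zero_only"
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if self.trait_mode not in TRAIT_MODES:
            raise ValueError(f"trait_mode must be one of {TRAIT_MODES}")
        if self.theta_policy not in THETA_POLICIES:
            raise ValueError(f"theta_policy must be one of {THETA_POLICIES}")
        self.sim.validate()

    def to_yaml(self, path) -> None:
        doc = {
            "trait_mode": self.trait_mode,
            "sim": self.sim.to_dict(),
            "model": {
                "disease_allele_freq": self.model.disease_allele_freq,
                "penetrances": list(self.model.penetrances),
            },
            "thresholds": dataclasses.asdict(self.thresholds),
            "theta_policy": self.theta_policy,
            "theta_grid": [float(t) for t in self.theta_grid],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        spec = cls(
            trait_mode=doc.get("trait_mode", "complete_null"),
            sim=SimulationConfig.from_dict(doc.get("sim", {})),
            model=TraitModel(
                disease_allele_freq=doc.get("model", {}).get(
                    "disease_allele_freq", 0.01
                ),
                penetrances=tuple(
                    doc.get("model", {}).get("penetrances", (0.05, 0.5, 0.5))
                ),
            ),
            thresholds=Thresholds(**doc.get("thresholds", {})),
            theta_policy=doc.get("theta_policy", "zero_only"),
            theta_grid=tuple(doc.get("theta_grid", DEFAULT_THETA_GRID)),
        )
        spec.validate()
        return spec


class StageError(RuntimeError):
    """An experiment stage failed; names the stage (and replicate if any)."""


def _stage(name: str, fn, *args, replicate: int | None = None, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        where = f"stage '{name}'"
        if replicate is not None:
            where += f" (replicate {replicate})"
        raise StageError(f"{where} failed: {exc}") from exc


def simulate_inputs(spec: ExperimentSpec):
    """Stages 1-4: pedigrees, genotypes + mask, trait replicates, founder MAF.

    Returns (peds, geno, affections, traits, freq_table); ``traits`` is None
    in complete_null mode.
    """
    spec.validate()
    sim = spec.sim
    peds = _stage("generate_pedigrees", synthetic_data.generate_pedigree_set, sim)
    for p in peds:
        if detect_loops(p):
            raise StageError(
                f"stage 'loop_check' failed: generated pedigree {p.family_id} "
                "contains loops"
            )
    markers = _stage("generate_markers", synthetic_data.generate_markers, sim)
    geno = _stage(
        "gene_drop", synthetic_data.gene_drop_genotypes, peds, markers, sim
    )
    geno = _stage("mask_ungenotyped", synthetic_data.mask_ungenotyped, geno, peds, sim)
    traits = None
    if spec.trait_mode == "dichotomized_polygenic":
        traits = _stage(
            "simulate_polygenic_trait", phenotypes.simulate_polygenic_trait,
            peds, sim,
        )
        affections = _stage(
            "dichotomize", phenotypes.dichotomize_by_founder_quantile,
            traits, peds, sim,
        )
        logger.info("dichotomization cutoff: %.4f", affections.cutoff)
    else:
        affections = _stage(
            "assign_random_affection", phenotypes.assign_random_affection,
            peds, sim,
        )
    freq_table = _stage("estimate_founder_maf", allele_freq.estimate_founder_maf,
                        geno, peds)
    return peds, geno, affections, traits, freq_table


def scan_replicates(
    spec: ExperimentSpec,
    scan: TwoPointScan,
    affections: phenotypes.AffectionReplicates,
    geno: genotypes.GenotypeMatrix,
    out_dir: Path | None = None,
) -> list[ReplicateSummary]:
    """Stage 5: per-replicate two-point LOD scan and replicate summaries."""
    marker_info = {m.marker_id: m for m in geno.markers}
    reps = []
    for r in range(affections.n_replicates):
        aff_map = affections.replicate_map(r)
        if spec.theta_policy == "zero_only":
            lod = _stage("linkage_scan", scan.lods, aff_map, 0.0, replicate=r)
            theta_used = 0.0
        else:
            mats = [
                _stage("linkage_scan", scan.lods, aff_map, t, replicate=r)
                for t in spec.theta_grid
            ]
            stackt = np.stack(mats)             # (n_theta, M, F)
            best = stackt.sum(axis=2).argmax(axis=0)  # per-marker argmax theta
            lod = stackt[best, np.arange(stackt.shape[1])]
            theta_used = float("nan")
        if out_dir is not None:
            write_lod_table(
                out_dir / f"lods_rep{r:03d}.tsv", geno, scan.family_ids,
                lod, theta_used,
            )
        stream = (
            res for res in _lod_stream(scan, lod, theta_used)
        )
        reps.append(
            summarize_replicate(stream, spec.thresholds, replicate=r,
                                marker_info=marker_info)
        )
    return reps


def _lod_stream(scan: TwoPointScan, lod: np.ndarray, theta: float):
    from .linkage import LodResult

    totals = lod.sum(axis=1)
    for j, mid in enumerate(scan.marker_ids):
        yield LodResult(
            marker_id=mid,
            theta=theta,
            family_lod=dict(zip(scan.family_ids, lod[j])),
            total_lod=float(totals[j]),
        )


def run_experiment(spec: ExperimentSpec) -> ExperimentSummary:
    """Run the whole experiment; write artifacts if ``spec.out_dir`` is set."""
    spec.validate()
    out_dir = Path(spec.out_dir) if spec.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    peds, geno, affections, traits, freq_table = simulate_inputs(spec)
    if out_dir is not None:
        write_pedigrees(peds, out_dir / "pedigrees.ped")
        genotypes.write_plink(geno, peds, out_dir / "genotypes")
        genotypes.write_vcf(geno, out_dir / "genotypes.vcf")
        allele_freq.write_freq_table(freq_table, out_dir / "founder_freq.tsv")
        phenotypes.write_phenotype_table(
            traits, affections, out_dir / "phenotypes.tsv"
        )
    scan = _stage("scan_setup", TwoPointScan, peds, geno, spec.model)
    reps = scan_replicates(spec, scan, affections, geno, out_dir)
    summary = _stage("summarize", summarize_experiment, reps, spec.thresholds)
    if out_dir is not None:
        write_report(summary, spec, reps, out_dir)
    return summary


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(
    summary: ExperimentSummary,
    spec: ExperimentSpec,
    reps: list[ReplicateSummary],
    out_dir,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec.to_yaml(out_dir / "config_echo.yaml")
    fields = {
        "trait_mode": spec.trait_mode,
        "seed": spec.sim.seed,
        "n_replicates": summary.n_replicates,
        "n_replicates_with_gws": summary.n_replicates_with_gws,
        "fwer_estimate": summary.fwer_estimate,
        "fwer_ci95_low": summary.fwer_ci95[0],
        "fwer_ci95_high": summary.fwer_ci95[1],
        "mean_significant": summary.mean_significant,
        "min_significant": summary.min_significant,
        "max_significant": summary.max_significant,
        "n_significant_total": summary.n_significant_total,
        "maf_lt_005": summary.maf_lt_005,
        "maf_lt_001": summary.maf_lt_001,
        "maf_at_floor": summary.maf_at_floor,
        "n_driver_1_2_suggestive": summary.n_driver_1_2_suggestive,
        "n_diffuse": summary.n_diffuse,
        "n_other_profile": summary.n_other_profile,
    }
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in fields.items():
            fh.write(f"{k}\t{v!r}\n" if isinstance(v, float) else f"{k}\t{v}\n")
    with open(out_dir / "significant_markers.tsv", "w") as fh:
        fh.write("replicate\tmarker_id\tchrom\tpos\ttotal_lod\testimated_maf\n")
        for r in reps:
            for rec in r.records:
                fh.write(
                    f"{r.replicate}\t{rec.marker_id}\t{rec.chromosome}\t"
                    f"{rec.position_bp}\t{rec.total_lod!r}\t{rec.estimated_maf!r}\n"
                )
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(_human_report(summary, spec))


def _human_report(summary: ExperimentSummary, spec: ExperimentSpec) -> str:
    s = summary
    lines = [
        f"Two-point null scan, trait mode: {spec.trait_mode}",
        f"seed: {spec.sim.seed}",
        "",
        f"Replicates analyzed: {s.n_replicates}",
    ]
    if s.n_replicates_with_gws == 0:
        lines.append(
            f"No replicate reached the GWS threshold "
            f"(LOD >= {s.thresholds.gws_lod})."
        )
    else:
        lines.append(
            f"{s.n_replicates_with_gws} of {s.n_replicates} replicates had at "
            f"least one GWS LOD score (>= {s.thresholds.gws_lod})."
        )
    lines += [
        f"FWER estimate: {s.fwer_estimate:.4f} "
        f"(Clopper-Pearson 95% CI {s.fwer_ci95[0]:.4f}-{s.fwer_ci95[1]:.4f})",
        f"Significant markers per replicate: mean {s.mean_significant:.2f} "
        f"(range {s.min_significant} to {s.max_significant})",
        f"Total significant markers: {s.n_significant_total}",
        "MAF strata of significant markers (nested): "
        f"<0.05: {s.maf_lt_005}; <0.01: {s.maf_lt_001}; "
        f"at floor 0.0001: {s.maf_at_floor}",
        "Family contribution profiles: "
        f"1-2 families > suggestive: {s.n_driver_1_2_suggestive}; "
        f"diffuse: {s.n_diffuse}; other: {s.n_other_profile}",
        "",
    ]
    return "\n".join(lines)


def parse_report(path) -> dict:
    """Read summary.tsv back; numeric fields round-trip exactly (repr floats)."""
    out: dict[str, object] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            k, v = line.rstrip("\n").split("\t")
            try:
                out[k] = int(v)
            except ValueError:
                try:
                    out[k] = float(v)
                except ValueError:
                    out[k] = v
    return out
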