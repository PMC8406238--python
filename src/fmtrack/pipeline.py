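"""End-to-end orchestration: configuration, staged runs, and the synthetic demo.

The pipeline wires the analysis stages together behind a single declarative
configuration (YAML or JSON) and a single global seed. Each stage receives a
stable child seed so stages are individually reproducible and replacing one
stage's parameters leaves the artifacts of unrelated stages byte-identical.
All outputs are flat TSV/JSON files named after the analysis they summarize
(fig2a_sources.tsv, fig3_patterns.tsv, fig5_reliability.tsv, ...) plus a
manifest recording parameters and output checksums.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, functions, iga, simulate, sources, strains
from ._util import ConfigurationError, FmtrackError, child_seeds
from .tables import (
    FeatureTable,
    SampleMetadata,
    read_feature_table,
    read_metadata,
    write_feature_table,
    write_metadata,
)

STAGES = ("simulate", "community", "sources", "strains", "functions", "iga")


@dataclasses.dataclass
class PipelineConfig:
    """Declarative run configuration; unknown keys are rejected.

    ``synthetic=True`` generates the cohort; otherwise ``feature_table`` and
    ``metadata`` must point at TSV inputs. Every threshold defaults to its
    module default.
    """

    out_dir: str = "fmtrack_out"
    seed: int = 0
    synthetic: bool = True
    feature_table: str | None = None
    metadata: str | None = None
    stages: tuple[str, ...] = STAGES
    # synthetic cohort scale
    n_patients: int = 12
    n_donors: int = 2
    n_features: int = 300
    n_function_families: int = 100
    iga_n_samples: int = 24
    iga_n_asvs: int = 150
    # thresholds (module defaults)
    min_count: int = 1
    window_days: int = 5
    window_size_bp: int = 1000
    depth_gate: float = 5.0
    coverage_gate: float = 50.0
    pseudocount: float = 1.0
    min_reads: int = 5
    min_samples: int = 5
    fdr: float = 0.1
    n_perm: int = 1000
    permanova_permutations: int = 999

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        obj = yaml.safe_load(text) or {}
        return cls.from_dict(obj)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**obj)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ConfigurationError(f"unknown stages: {sorted(bad)}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest (also written to disk).

    Deterministic given (inputs, config, seed): the global seed fans out to
    per-stage child seeds. On stage failure the run aborts with the stage
    name and cause; artifacts of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, child_seeds(config.seed, len(STAGES))))
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": {k: int(v) for k, v in seeds.items()},
        "outputs": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        runner = _STAGE_RUNNERS[stage]
        try:
            runner(config, seeds[stage], out, state)
        except FmtrackError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ConfigurationError(f"stage {stage!r} failed: {exc}") from exc
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or not path.is_file():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, seed: int, out: Path, state: dict) -> None:
    if config.synthetic:
        table, meta, truth = simulate.simulate_cohort(
            n_patients=config.n_patients,
            n_donors=config.n_donors,
            n_features=config.n_features,
            seed=seed,
        )
        truth_obj = {
            "provenance": {p: s.to_dict() for p, s in sorted(truth.provenance.items())},
            "fate": {p: s.to_dict() for p, s in sorted(truth.fate.items())},
            "donor_partition": {
                p: s.to_dict() for p, s in sorted(truth.donor_partition.items())
            },
            "params": truth.params,
        }
        with open(out / "cohort_truth.json", "w") as fh:
            json.dump(truth_obj, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        if not config.feature_table or not config.metadata:
            raise ConfigurationError(
                "non-synthetic runs require feature_table and metadata paths"
            )
        table = read_feature_table(config.feature_table)
        meta = read_metadata(config.metadata)
        meta.check_covers(table)
    write_feature_table(table, out / "feature_table.tsv")
    write_metadata(meta, out / "metadata.tsv")
    state["table"], state["meta"] = table, meta


def _require_cohort(config: PipelineConfig, state: dict) -> tuple[FeatureTable, SampleMetadata]:
    if "table" not in state:
        raise ConfigurationError("this stage requires the simulate stage (cohort inputs)")
    return state["table"], state["meta"]


def _stage_community(config: PipelineConfig, seed: int, out: Path, state: dict) -> None:
    table, meta = _require_cohort(config, state)
    rel = table.to_relative()
    alpha = pd.DataFrame(
        {
            "shannon": community.shannon(table),
            "richness": community.richness(table, config.min_count),
        }
    )
    alpha.index.name = "sample_id"
    _write_tsv(alpha, out / "fig1e_alpha_diversity.tsv")
    dm = community.bray_curtis(rel)
    _write_tsv(dm.to_frame(), out / "bray_curtis.tsv")
    ord_res = community.pcoa(dm, k=2)
    coords = ord_res.coordinates.copy()
    coords.index.name = "sample_id"
    _write_tsv(coords, out / "fig1b_pcoa.tsv")
    grouping = meta.frame.loc[list(dm.ids), "subject_id"]
    perm = community.permanova(
        dm, grouping, n_perm=config.permanova_permutations, seed=seed
    )
    # distance-to-donor trajectories, compared between arms in 5-day windows
    donor_samples = [
        s for s in dm.ids if meta.frame.loc[s, "role"] == "donor"
    ]
    rows = []
    for s in dm.ids:
        if meta.frame.loc[s, "role"] != "patient":
            continue
        d = float(np.mean([dm.between(s, ds) for ds in donor_samples]))
        rows.append(
            {"subject_id": meta.frame.loc[s, "subject_id"],
             "day": meta.day_of(s), "value": d}
        )
    traj = pd.DataFrame(rows)
    windowed = community.windowed_mean(traj, window=config.window_days)
    arm_of = (
        meta.frame[meta.frame["role"] == "patient"]
        .drop_duplicates("subject_id")
        .set_index("subject_id")["arm"]
    )
    comparison = community.compare_arms(windowed, arm_of)
    _write_tsv(comparison, out / "fig1d_donor_distance_windows.tsv", index=False)
    with open(out / "community_summary.json", "w") as fh:
        json.dump(
            {
                "permanova_pseudo_f": perm.statistic,
                "permanova_p": perm.p_value,
                "pcoa_proportion_explained": list(
                    np.round(ord_res.proportion_explained[:2], 6)
                ),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")


def _stage_sources(config: PipelineConfig, seed: int, out: Path, state: dict) -> None:
    table, meta = _require_cohort(config, state)
    frac_frames, colon_frames, assign_rows = [], [], []
    assignments = {}
    for patient in meta.subjects(role="patient"):
        assignment = sources.assign_sources(
            table, meta, patient, min_count=config.min_count
        )
        assignments[patient] = assignment
        for feat, src in assignment.source.items():
            assign_rows.append({"patient_id": patient, "feature_id": feat, "source": src})
        frac = sources.source_fractions(assignment, table, meta, min_count=config.min_count)
        frac.insert(0, "patient_id", patient)
        frac_frames.append(frac)
        if meta.samples_of(patient, phases=("followup",)):
            calls = sources.classify_colonization(
                assignment, table, meta, min_count=config.min_count
            ).reset_index()
            calls.insert(0, "patient_id", patient)
            colon_frames.append(calls)
    _write_tsv(pd.DataFrame(assign_rows), out / "source_assignments.tsv", index=False)
    _write_tsv(pd.concat(frac_frames, ignore_index=True), out / "fig2a_sources.tsv",
               index=False)
    if colon_frames:
        _write_tsv(pd.concat(colon_frames, ignore_index=True),
                   out / "fig2b_colonization.tsv", index=False)
    state["assignments"] = assignments


def _stage_strains(config: PipelineConfig, seed: int, out: Path, state: dict) -> None:
    """Flexible-genome demonstration on simulated strain mixtures.

    One scenario per colonization/dominance pattern: a donor strain and a
    patient strain with disjoint accessory segments, mixed over time per the
    pattern, plus a depth crash for the insufficient branches.
    """
    scenarios = {
        # per timepoint: (donor strain weight, patient strain weight, depth scale);
        # t0 is the pre-FMT context, the last timepoint is follow-up. A sample
        # dominated by the donor strain matches the donor; one dominated by the
        # patient strain is ambiguous against the donor (disjoint accessory
        # segments); a depth crash makes the comparison insufficient.
        "persistent_dominance": [(0, 1, 1), (1, 0, 1), (1, 0, 1), (1, 0, 1), (1, 0, 1)],
        "temporary_dominance": [(0, 1, 1), (1, 0, 1), (1, 0, 1), (0, 1, 0.05), (0, 1, 0.05)],
        "persistent_colonization_temporary_dominance":
            [(0, 1, 1), (1, 0, 1), (1, 0, 1), (0, 1, 1), (0, 1, 1)],
        "ambiguous_persistent": [(0, 1, 1), (0, 1, 1), (0, 1, 1), (0, 1, 1), (0, 1, 1)],
        "ambiguous_temporary": [(0, 1, 1), (0, 1, 1), (0, 1, 1), (0, 1, 0.05), (0, 1, 0.05)],
        "no_colonization": [(0, 1, 0.05), (0, 1, 0.05), (0, 1, 0.05), (0, 1, 0.05),
                            (0, 1, 0.05)],
    }
    accessory = {"donor_strain": range(80, 88), "patient_strain": range(90, 98)}
    rows, pattern_rows = [], []
    stage_seeds = child_seeds(seed, len(scenarios) + 1)
    donor_profiles = simulate.simulate_depth_profiles(
        genome_length=100_000,
        window=config.window_size_bp,
        strain_accessory_sets=accessory,
        mixtures={"donor.t1": {"donor_strain": 1.0}, "donor.t2": {"donor_strain": 1.0}},
        mean_depth=30.0,
        seed=stage_seeds[-1],
        genome_id="genomeA",
    )
    for i, (name, plan) in enumerate(sorted(scenarios.items())):
        mixtures = {}
        for t, (wd, wp, scale) in enumerate(plan):
            mixtures[f"{name}.t{t}"] = {
                "donor_strain": wd * scale,
                "patient_strain": wp * scale,
            }
        profiles = simulate.simulate_depth_profiles(
            genome_length=100_000,
            window=config.window_size_bp,
            strain_accessory_sets=accessory,
            mixtures=mixtures,
            mean_depth=30.0,
            seed=stage_seeds[i],
            genome_id="genomeA",
        )
        ordered = [profiles[f"{name}.t{t}"] for t in range(len(plan))]
        # first timepoint is pre-FMT context; verdicts start at t1, last is follow-up
        post = ordered[1:]
        followup = [False] * (len(post) - 1) + [True]
        traj = strains.donor_match_trajectory(
            post, list(donor_profiles.values()), depth_gate=config.depth_gate,
            followup_flags=followup,
        )
        pattern = strains.classify_pattern(
            [p.consensus for p in traj], followup, patient_id=name, genome_id="genomeA"
        )
        pattern_rows.append(
            {"scenario": name, "pattern": pattern.pattern, "label": pattern.label}
        )
        for point in traj:
            for comp in point.per_donor:
                rows.append(
                    {"scenario": name, "patient_sample": comp.sample_a,
                     "donor_sample": comp.sample_b, "verdict": comp.verdict,
                     "median_patient": comp.median_a, "median_donor": comp.median_b,
                     "consensus": point.consensus, "followup": point.followup}
                )
    _write_tsv(pd.DataFrame(rows), out / "fig3_comparisons.tsv", index=False)
    _write_tsv(pd.DataFrame(pattern_rows), out / "fig3_patterns.tsv", index=False)
    # haplotype post-processing demo: pooling plus median-depth normalization
    freq = pd.DataFrame(
        {"strain_1": [0.6, 0.55, 0.5, 0.5, 0.45], "strain_2": [0.4, 0.45, 0.5, 0.5, 0.55]},
        index=["baseline", "induction", "capsule", "alternate_donor", "followup"],
    )
    depth = pd.Series([80.0, 120.0, 90.0, 60.0, 70.0], index=freq.index)
    norm = strains.normalize_strain_frequencies(
        freq, depth, coverage_gate=config.coverage_gate
    )
    if norm is not None:
        norm.index.name = "bin"
        _write_tsv(norm, out / "strainfinder_normalized.tsv")


def _stage_functions(config: PipelineConfig, seed: int, out: Path, state: dict) -> None:
    profiles, meta, cmap, _truth = simulate.simulate_function_profiles(
        n_families=config.n_function_families,
        n_patients=config.n_patients,
        n_donors=config.n_donors,
        seed=seed,
    )
    frames = []
    for patient in meta.subjects(role="patient"):
        for category in ("glycoside_hydrolase", "antimicrobial_resistance",
                         "virulence_factor"):
            _, frac = functions.function_sources(profiles, meta, cmap, patient, category)
            frac.insert(0, "category", category)
            frac.insert(0, "patient_id", patient)
            frames.append(frac)
    _write_tsv(pd.concat(frames, ignore_index=True), out / "fig4_sources.tsv", index=False)
    rich_cmp = functions.compare_category_richness(
        profiles, meta, cmap, "glycoside_hydrolase", window=config.window_days
    )
    _write_tsv(rich_cmp, out / "fig4f_gh_richness_windows.tsv", index=False)
    quin = functions.quinolone_response(profiles, meta, cmap)
    _write_tsv(quin.per_patient, out / "fig4k_quinolone_deltas.tsv")
    with open(out / "functions_summary.json", "w") as fh:
        json.dump(
            {"quinolone_u": quin.u, "quinolone_p": quin.p_value,
             "n_patients": int(len(quin.per_patient))},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")


def _stage_iga(config: PipelineConfig, seed: int, out: Path, state: dict) -> None:
    seeds = child_seeds(seed, 3)
    latent = np.zeros((config.iga_n_samples, config.iga_n_asvs))
    n_coated = max(2, config.iga_n_asvs // 10)
    n_uncoated = max(2, config.iga_n_asvs // 20)
    latent[:, :n_coated] = 2.0
    latent[:, n_coated:n_coated + n_uncoated] = -2.0
    coated, uncoated, truth = simulate.simulate_iga_fractions(
        n_samples=config.iga_n_samples,
        n_asvs=config.iga_n_asvs,
        latent_scores=latent,
        seed=seeds[0],
    )
    scores = iga.coating_score(
        coated, uncoated, pseudocount=config.pseudocount, min_reads=config.min_reads
    )
    out_scores = scores.scores.copy()
    out_scores.index.name = "sample_id"
    _write_tsv(out_scores, out / "iga_scores.tsv")
    rel = iga.reliability(scores, min_samples=config.min_samples, fdr=config.fdr)
    _write_tsv(rel, out / "fig5_reliability.tsv")
    perm = iga.permutation_test(
        scores, n_perm=config.n_perm, seed=seeds[1],
        min_samples=config.min_samples, fdr=config.fdr,
    )
    with open(out / "iga_permutation.json", "w") as fh:
        json.dump(
            {"observed_reliable": perm.observed_count, "p_value": perm.p_value,
             "n_permutations": perm.n_permutations},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    # pairwise coating correlations between consecutive samples
    cors = []
    ids = scores.sample_ids
    for a, b in zip(ids[:-1], ids[1:]):
        res = iga.coating_correlation(scores.scores.loc[a], scores.scores.loc[b])
        if res is not None:
            cors.append({"sample_a": a, "sample_b": b, "r": res.r,
                         "p_value": res.p_value, "n": res.n})
    _write_tsv(pd.DataFrame(cors), out / "iga_correlations.tsv", index=False)


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "community": _stage_community,
    "sources": _stage_sources,
    "strains": _stage_strains,
    "functions": _stage_functions,
    "iga": _stage_iga,
}


def synth_demo(seed: int, out_dir: str, n_perm: int = 500) -> dict:
    """Small fully synthetic end-to-end run (all stages, doc-scale sizes).

    Deterministic given the seed: re-running with the same seed reproduces
    byte-identical outputs (verified through the manifest checksums).
    """
    config = PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        synthetic=True,
        n_patients=8,
        n_features=150,
        n_function_families=60,
        iga_n_samples=16,
        iga_n_asvs=80,
        n_perm=n_perm,
        permanova_permutations=499,
    )
    return run_pipeline(config)
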