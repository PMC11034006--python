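"""Full study orchestration: six training samples, six pwC sets, all tables.

The experiment mirrors the multi-dataset design: four training-eligible
datasets plus one unseen external dataset are generated; within each
training dataset an age-matched, sex-balanced sample is built and split
75/25; two compound samples (a large one pooling all per-dataset train
subjects and a smaller one at the same dataset/sex/age composition) are
assembled. Each of the six training samples yields (i) a within-sample
CV accuracy map and (ii) a set of final per-parcel models (rbf kernel
only) that are applied across samples: single-dataset pwCs to the other
datasets' full matched samples, compound pwCs to the held-out 25%
splits, and every pwC to the unseen dataset. Dice profiles, tile
summaries (mean top-fraction accuracy and wmDice per train/eval pair)
and Bonferroni-gated t-test comparisons complete the bundle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .connectome import stack_profiles
from .consistency import (
    DEFAULT_THRESHOLDS,
    DiceProfile,
    dice_profile,
    mean_top_accuracy,
    top_fraction,
)
from .errors import ConfigurationError
from .pwc import (
    AccuracyMap,
    ClassifierConfig,
    TrainedParcelModelSet,
    cv_parcel_accuracy,
    fit_final_models,
    test_across_sample,
)
from .samples import SampleDefinition, build_compound, match_sexes_by_age, split_holdout
from .stats import compare_condition_families
from .synthetic import DatasetSpec, EffectSpec, StudyData, make_multisite_study, subseed

logger = logging.getLogger(__name__)

COMPOUND_SMALL = "compound_small"
COMPOUND_LARGE = "compound_large"

#: Default heterogeneous-site study: four training-eligible sites with
#: distinct age ranges and site effects (offset/scale/noise in Fisher-z
#: units) plus one unseen site. The heterogeneity is deliberately large
#: enough, relative to the sex effect, that single-site classifiers pick
#: up site-specific structure — the mechanism the compound-training
#: comparison probes.
DEFAULT_SITE_PARAMS: tuple[dict, ...] = (
    dict(name="site_a", age_range=(22.0, 37.0), female_fraction=0.5,
         site_offset=0.10, site_scale=1.10, noise_sd=0.45),
    dict(name="site_b", age_range=(21.0, 35.0), female_fraction=0.5,
         site_offset=-0.10, site_scale=0.90, noise_sd=0.55),
    dict(name="site_c", age_range=(20.0, 83.0), female_fraction=0.5,
         site_offset=0.20, site_scale=1.05, noise_sd=0.65),
    dict(name="site_d", age_range=(21.0, 85.0), female_fraction=0.5,
         site_offset=-0.20, site_scale=0.95, noise_sd=0.50),
    dict(name="site_e", age_range=(20.0, 26.0), female_fraction=0.58,
         site_offset=0.05, site_scale=1.00, noise_sd=0.60, unseen=True),
)


def default_dataset_specs(
    n_per_dataset: int = 200, n_unseen: int | None = None
) -> tuple[DatasetSpec, ...]:
    """The default five-site study at a configurable per-site size."""
    specs = []
    for params in DEFAULT_SITE_PARAMS:
        n = n_per_dataset
        if params.get("unseen") and n_unseen is not None:
            n = n_unseen
        specs.append(DatasetSpec(n_subjects=n, **params))
    return tuple(specs)


def default_effects(n_parcels: int = 60, n_signal: int = 6) -> EffectSpec:
    """Evenly spaced signal parcels with the default effect sizes."""
    signal = tuple(
        int(i) for i in np.linspace(0, n_parcels - 1, n_signal).round()
    )
    return EffectSpec(n_parcels=n_parcels, signal_parcels=signal)


@dataclass
class ExperimentConfig:
    """Everything needed to run the study end to end."""

    datasets: tuple[DatasetSpec, ...]
    effects: EffectSpec
    seed: int = 0
    caliper: float = 3.0
    train_fraction: float = 0.75
    compound_sizes: tuple[int, int] | None = None  # (small, large); None = auto
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    restrict_cross_sample_kernel: bool = True
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    top_frac: float = 0.10
    alpha: float = 0.05
    single_eval_full: bool = True
    n_jobs: int = 1

    #: size ratio large:small used when compound_sizes is None, matching
    #: the 2190:854 ratio of the full-scale design.
    AUTO_RATIO = 2190.0 / 854.0

    def __post_init__(self) -> None:
        self.datasets = tuple(self.datasets)
        if sum(d.unseen for d in self.datasets) != 1:
            raise ConfigurationError("exactly one dataset must be unseen")
        if len(self.datasets) < 3:
            raise ConfigurationError("need at least two training datasets + unseen")

    @classmethod
    def default(cls, seed: int = 0, n_parcels: int = 60,
                n_per_dataset: int = 200, n_signal: int = 6,
                **kwargs) -> "ExperimentConfig":
        return cls(
            datasets=default_dataset_specs(n_per_dataset),
            effects=default_effects(n_parcels, n_signal),
            seed=seed,
            **kwargs,
        )

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        eff = {
            "n_parcels": int(self.effects.n_parcels),
            "signal_parcels": [int(i) for i in self.effects.signal_parcels],
            "sex_effect_size": float(self.effects.sex_effect_size),
            "age_slope": float(self.effects.age_slope),
        }
        clf = asdict(self.classifier)
        clf["kernels"] = list(clf["kernels"])
        clf["C_grid"] = [float(c) for c in clf["C_grid"]]
        clf["gamma_grid"] = [
            g if g == "scale" else float(g) for g in clf["gamma_grid"]
        ]
        return {
            "seed": int(self.seed),
            "datasets": [
                {
                    "name": d.name,
                    "n_subjects": int(d.n_subjects),
                    "age_range": [float(a) for a in d.age_range],
                    "female_fraction": float(d.female_fraction),
                    "site_offset": float(d.site_offset),
                    "site_scale": float(d.site_scale),
                    "noise_sd": float(d.noise_sd),
                    "unseen": bool(d.unseen),
                }
                for d in self.datasets
            ],
            "effects": eff,
            "samples": {
                "caliper": float(self.caliper),
                "train_fraction": float(self.train_fraction),
                "compound_sizes": (
                    [int(s) for s in self.compound_sizes]
                    if self.compound_sizes
                    else None
                ),
            },
            "classifier": clf,
            "analysis": {
                "thresholds": [float(t) for t in self.thresholds],
                "top_fraction": float(self.top_frac),
                "alpha": float(self.alpha),
                "restrict_cross_sample_kernel": self.restrict_cross_sample_kernel,
                "single_eval_full": self.single_eval_full,
            },
            "n_jobs": self.n_jobs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        datasets = tuple(
            DatasetSpec(
                name=ds["name"],
                n_subjects=int(ds["n_subjects"]),
                age_range=tuple(ds["age_range"]),
                female_fraction=float(ds.get("female_fraction", 0.5)),
                site_offset=float(ds.get("site_offset", 0.0)),
                site_scale=float(ds.get("site_scale", 1.0)),
                noise_sd=float(ds.get("noise_sd", 0.5)),
                unseen=bool(ds.get("unseen", False)),
            )
            for ds in d["datasets"]
        )
        eff = dict(d["effects"])
        if "signal_parcels" not in eff and "n_signal" in eff:
            n_signal = int(eff.pop("n_signal"))
            eff["signal_parcels"] = [
                int(i)
                for i in np.linspace(0, eff["n_parcels"] - 1, n_signal).round()
            ]
        effects = EffectSpec(
            n_parcels=int(eff["n_parcels"]),
            signal_parcels=tuple(eff["signal_parcels"]),
            sex_effect_size=float(eff.get("sex_effect_size", 0.4)),
            age_slope=float(eff.get("age_slope", 0.004)),
        )
        smp = d.get("samples", {})
        clf_d = dict(d.get("classifier", {}))
        for key in ("kernels", "C_grid", "gamma_grid"):
            if key in clf_d:
                clf_d[key] = tuple(clf_d[key])
        ana = d.get("analysis", {})
        sizes = smp.get("compound_sizes")
        return cls(
            datasets=datasets,
            effects=effects,
            seed=int(d.get("seed", 0)),
            caliper=float(smp.get("caliper", 3.0)),
            train_fraction=float(smp.get("train_fraction", 0.75)),
            compound_sizes=tuple(int(s) for s in sizes) if sizes else None,
            classifier=ClassifierConfig(**clf_d),
            restrict_cross_sample_kernel=bool(
                ana.get("restrict_cross_sample_kernel", True)
            ),
            thresholds=tuple(ana.get("thresholds", DEFAULT_THRESHOLDS)),
            top_frac=float(ana.get("top_fraction", 0.10)),
            alpha=float(ana.get("alpha", 0.05)),
            single_eval_full=bool(ana.get("single_eval_full", True)),
            n_jobs=int(d.get("n_jobs", 1)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ExperimentResult:
    """In-memory bundle of everything one experiment run produced."""

    config: ExperimentConfig
    study: StudyData
    samples: dict[str, SampleDefinition]
    within_maps: dict[str, AccuracyMap]
    across_maps: dict[tuple[str, str], AccuracyMap]
    dice: dict[tuple[str, str], DiceProfile]
    tiles: pd.DataFrame
    comparisons: pd.DataFrame
    train_order: tuple[str, ...]

    def unseen_ranking(self) -> pd.DataFrame:
        """Per-pwC mean top-fraction accuracy and wmDice on the unseen set."""
        unseen = self.study.unseen
        rows = []
        for train in self.train_order:
            amap = self.across_maps[(train, unseen)]
            prof = self.dice[(train, unseen)]
            rows.append(
                {
                    "train_sample": train,
                    "mean_top_accuracy": mean_top_accuracy(
                        amap, self.config.top_frac
                    ),
                    "wm_dice": prof.wm_dice,
                }
            )
        return pd.DataFrame(rows)


def _sample_arrays(study: StudyData, profile_cache: dict, sample: SampleDefinition):
    """Feature blocks, labels, ages, ids for the subjects of a sample."""
    demo = study.demographics().set_index("subject_id")
    blocks, labels, ages, ids = [], [], [], []
    # gather per dataset to keep slicing cheap
    order = {sid: k for k, sid in enumerate(sample.subject_ids)}
    rows = demo.loc[list(sample.subject_ids)]
    for ds in rows["dataset"].unique():
        cohort = study.cohorts[ds]
        if ds not in profile_cache:
            profile_cache[ds] = stack_profiles(cohort.connectomes)
        sid_to_row = {
            sid: i for i, sid in enumerate(cohort.demographics["subject_id"])
        }
        members = [sid for sid in sample.subject_ids if sid in sid_to_row]
        idx = [sid_to_row[s] for s in members]
        blocks.append(profile_cache[ds][idx])
        sub = cohort.demographics.iloc[idx]
        labels.extend(sub["sex"])
        ages.extend(sub["age"])
        ids.extend(members)
    x = np.concatenate(blocks, axis=0)
    # restore the sample's own subject order
    perm = np.argsort([order[s] for s in ids], kind="stable")
    return (
        x[perm],
        np.asarray(labels, dtype=object)[perm],
        np.asarray(ages, dtype=float)[perm],
        tuple(np.asarray(ids, dtype=object)[perm]),
    )


def _full_sample(study: StudyData, name: str) -> SampleDefinition:
    demo = study.cohorts[name].demographics
    return SampleDefinition(
        name=f"{name}_full",
        role="test",
        subject_ids=tuple(demo["subject_id"]),
        source_counts={name: len(demo)},
    )


def build_samples(
    config: ExperimentConfig, study: StudyData
) -> tuple[dict[str, SampleDefinition], dict[str, SampleDefinition]]:
    """Matched per-dataset samples, 75/25 splits and the two compounds.

    Returns (training samples by name, evaluation samples by name).
    Training names: the four dataset names plus compound_small /
    compound_large; evaluation names: per-dataset matched-full samples,
    per-dataset held-out test splits, and the unseen cohort.
    """
    trains: dict[str, SampleDefinition] = {}
    evals: dict[str, SampleDefinition] = {}
    per_dataset_train: dict[str, SampleDefinition] = {}
    for name in study.training_eligible:
        cohort = study.cohorts[name]
        matched = match_sexes_by_age(
            cohort.demographics, config.caliper, name=f"{name}_matched"
        )
        matched_demo = (
            cohort.demographics.set_index("subject_id")
            .loc[list(matched.subject_ids)]
            .reset_index()
        )
        train, test = split_holdout(
            matched_demo,
            config.train_fraction,
            seed=subseed(config.seed, f"split:{name}"),
            name_prefix=name,
        )
        per_dataset_train[name] = train
        trains[name] = SampleDefinition(
            name=name, role="train", subject_ids=train.subject_ids,
            source_counts=dict(train.source_counts),
        )
        evals[f"{name}_test"] = test
        evals[f"{name}_full"] = SampleDefinition(
            name=f"{name}_full", role="test",
            subject_ids=matched.subject_ids,
            source_counts={name: len(matched)},
        )
    total = sum(len(s) for s in per_dataset_train.values())
    if config.compound_sizes is None:
        sizes = (int(round(total / ExperimentConfig.AUTO_RATIO)), total)
    else:
        sizes = config.compound_sizes
    pooled_demo = study.demographics()
    trains[COMPOUND_SMALL] = build_compound(
        per_dataset_train, pooled_demo, sizes[0],
        seed=subseed(config.seed, "compound_small"), name=COMPOUND_SMALL,
    )
    trains[COMPOUND_LARGE] = build_compound(
        per_dataset_train, pooled_demo, sizes[1],
        seed=subseed(config.seed, "compound_large"), name=COMPOUND_LARGE,
    )
    evals[study.unseen] = _full_sample(study, study.unseen)
    return trains, evals


def _eval_plan(
    config: ExperimentConfig, study: StudyData, train_name: str
) -> list[str]:
    """Evaluation sample names for one training sample."""
    singles = list(study.training_eligible)
    plan: list[str] = []
    if train_name in (COMPOUND_SMALL, COMPOUND_LARGE):
        plan.extend(f"{ds}_test" for ds in singles)
    else:
        others = [ds for ds in singles if ds != train_name]
        suffix = "_full" if config.single_eval_full else "_test"
        plan.extend(f"{ds}{suffix}" for ds in others)
    plan.append(study.unseen)
    return plan


def _eval_dataset(eval_name: str) -> str:
    for suffix in ("_test", "_full"):
        if eval_name.endswith(suffix):
            return eval_name[: -len(suffix)]
    return eval_name


def run_experiment(
    config: ExperimentConfig, out_dir=None
) -> ExperimentResult:
    """Run the full study and (optionally) write the artifact bundle."""
    t0 = time.perf_counter()
    study = make_multisite_study(config.datasets, config.effects, config.seed)
    logger.info("generated %d cohorts in %.1fs", len(study.cohorts),
                time.perf_counter() - t0)

    trains, evals = build_samples(config, study)
    train_order = tuple(study.training_eligible) + (COMPOUND_SMALL, COMPOUND_LARGE)

    profile_cache: dict[str, np.ndarray] = {}
    within_maps: dict[str, AccuracyMap] = {}
    across_maps: dict[tuple[str, str], AccuracyMap] = {}
    dice: dict[tuple[str, str], DiceProfile] = {}

    for train_name in train_order:
        stage_t = time.perf_counter()
        sample = trains[train_name]
        try:
            x, labels, ages, ids = _sample_arrays(study, profile_cache, sample)
            cfg = ClassifierConfig(
                **{
                    **asdict(config.classifier),
                    "seed": subseed(config.seed, f"cv:{train_name}"),
                }
            )
            within_maps[train_name] = AccuracyMap(
                cv_parcel_accuracy(
                    x, labels, ages, cfg, n_jobs=config.n_jobs,
                    sample_name=train_name,
                ).values,
                train_sample=train_name,
                eval_sample=train_name,
                mode="within_cv",
            )
            models = fit_final_models(
                x, labels, ages, cfg,
                restrict_rbf=config.restrict_cross_sample_kernel,
                subject_ids=ids, sample_name=train_name, n_jobs=config.n_jobs,
            )
            for eval_name in _eval_plan(config, study, train_name):
                ex, elab, eage, eids = _sample_arrays(
                    study, profile_cache, evals[eval_name]
                )
                amap = test_across_sample(
                    models, ex, elab, eage, test_subject_ids=eids,
                    eval_sample=eval_name,
                )
                across_maps[(train_name, eval_name)] = amap
                dice[(train_name, eval_name)] = dice_profile(
                    within_maps[train_name], amap, config.thresholds
                )
        except Exception as exc:
            raise RuntimeError(
                f"stage pwc[{train_name}] failed: {exc}"
            ) from exc
        logger.info("pwC %s done in %.1fs", train_name,
                    time.perf_counter() - stage_t)

    tiles = _tiles_frame(config, train_order, within_maps, across_maps, dice)
    comparisons = _comparisons_frame(config, study, train_order, across_maps)

    result = ExperimentResult(
        config=config, study=study, samples={**trains, **evals},
        within_maps=within_maps, across_maps=across_maps, dice=dice,
        tiles=tiles, comparisons=comparisons, train_order=train_order,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    logger.info("experiment finished in %.1fs", time.perf_counter() - t0)
    return result


def _tiles_frame(config, train_order, within_maps, across_maps, dice):
    rows = []
    for train_name in train_order:
        wmap = within_maps[train_name]
        rows.append(
            {
                "train_sample": train_name,
                "eval_sample": train_name,
                "mode": "within_cv",
                "mean_top_accuracy": mean_top_accuracy(wmap, config.top_frac),
                "wm_dice": np.nan,
            }
        )
        for (tr, ev), amap in across_maps.items():
            if tr != train_name:
                continue
            prof = dice[(tr, ev)]
            rows.append(
                {
                    "train_sample": tr,
                    "eval_sample": ev,
                    "mode": "across_sample",
                    "mean_top_accuracy": mean_top_accuracy(amap, config.top_frac),
                    "wm_dice": np.nan if prof.wm_dice is None else prof.wm_dice,
                }
            )
    return pd.DataFrame(rows)


def _comparisons_frame(config, study, train_order, across_maps):
    """Comparison families: horizontal per pwC, vertical per test dataset."""
    tile_vectors = {}
    for (tr, ev), amap in across_maps.items():
        sel = top_fraction(amap, config.top_frac)
        tile_vectors[f"{tr}->{ev}"] = amap.values[sel]
    if any(len(v) < 2 for v in tile_vectors.values()):
        logger.warning(
            "top-fraction vectors have < 2 parcels; skipping t-test comparisons"
        )
        return pd.DataFrame(
            columns=["family", "cond_a", "cond_b", "t", "df", "p", "gate",
                     "significant"]
        )

    families: dict[str, list[tuple[str, str]]] = {}
    # horizontal: each pwC compared across its evaluation samples
    for train_name in train_order:
        conds = [
            f"{tr}->{ev}" for (tr, ev) in across_maps if tr == train_name
        ]
        pairs = [
            (conds[i], conds[j])
            for i in range(len(conds))
            for j in range(i + 1, len(conds))
        ]
        families[f"horizontal:{train_name}"] = pairs
    # vertical: each evaluation dataset compared across pwCs
    by_dataset: dict[str, list[str]] = {}
    for (tr, ev) in across_maps:
        by_dataset.setdefault(_eval_dataset(ev), []).append(f"{tr}->{ev}")
    for ds, conds in by_dataset.items():
        pairs = [
            (conds[i], conds[j])
            for i in range(len(conds))
            for j in range(i + 1, len(conds))
        ]
        families[f"vertical:{ds}"] = pairs
    return compare_condition_families(
        tile_vectors, families, alpha=config.alpha, on_degenerate="nan"
    )


def _write_bundle(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    study = result.study
    pio.write_demographics(study.demographics(), out_dir / "demographics.csv")
    pio.write_samples(result.samples.values(), out_dir / "samples.csv")
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    for name, amap in result.within_maps.items():
        pio.write_accuracy_map(
            amap, maps_dir / f"within__{name}.tsv",
            extra_meta={"seed": result.config.seed},
        )
    for (tr, ev), amap in result.across_maps.items():
        pio.write_accuracy_map(
            amap, maps_dir / f"across__{tr}__{ev}.tsv",
            extra_meta={"seed": result.config.seed},
        )
    dice_dir = out_dir / "dice"
    dice_dir.mkdir(exist_ok=True)
    for (tr, ev), prof in result.dice.items():
        pio.write_dice_profile(prof, dice_dir / f"dice__{tr}__{ev}.tsv")
    result.tiles.to_csv(out_dir / "tiles.csv", index=False)
    result.comparisons.to_csv(out_dir / "comparisons.csv", index=False)
    result.config.to_yaml(out_dir / "config.yaml")
    manifest = {
        "seed": result.config.seed,
        "n_parcels": result.config.effects.n_parcels,
        "train_samples": list(result.train_order),
        "unseen": study.unseen,
        "files": sorted(
            str(p.relative_to(out_dir)) for p in out_dir.rglob("*") if p.is_file()
        ),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def matched_site_probe(
    seed: int,
    n_parcels: int = 20,
    n_signal: int = 4,
    n_per_site: int = 150,
    classifier: ClassifierConfig | None = None,
    top_frac: float = 0.10,
) -> tuple[float, float]:
    """Quantify the "matching datasets" phenomenon on a 3-site construction.

    Site A and site B share identical site parameters while site C is
    shifted (different offset/scale/noise and age range). A pwC trained
    on site A's age-matched sample is applied to both B and C; the
    returned pair is (mean top-fraction accuracy on the matched site B,
    same on the shifted site C). When site effects drive generalization,
    the first exceeds the second.
    """
    if classifier is None:
        classifier = ClassifierConfig(
            kernels=("rbf",), C_grid=(0.1, 1.0, 10.0), gamma_grid=("scale",),
            outer_folds=5, repeats=1, inner_folds=3, seed=0,
        )
    shared = dict(site_offset=0.05, site_scale=1.0, noise_sd=0.5)
    specs = (
        DatasetSpec("probe_a", n_per_site, (20.0, 60.0), **shared),
        DatasetSpec("probe_b", n_per_site, (20.0, 60.0), **shared),
        DatasetSpec(
            "probe_c", n_per_site, (40.0, 80.0), site_offset=0.4,
            site_scale=0.8, noise_sd=0.7, unseen=True,
        ),
    )
    effects = default_effects(n_parcels, n_signal)
    study = make_multisite_study(specs, effects, seed)

    cohort_a = study.cohorts["probe_a"]
    matched = match_sexes_by_age(cohort_a.demographics, caliper=3.0)
    cache: dict[str, np.ndarray] = {}
    x, labels, ages, ids = _sample_arrays(study, cache, matched)
    cfg = ClassifierConfig(
        **{**asdict(classifier), "seed": subseed(seed, "probe")}
    )
    models = fit_final_models(
        x, labels, ages, cfg, subject_ids=ids, sample_name="probe_a"
    )
    out = []
    for name in ("probe_b", "probe_c"):
        ex, elab, eage, eids = _sample_arrays(
            study, cache, _full_sample(study, name)
        )
        amap = test_across_sample(
            models, ex, elab, eage, test_subject_ids=eids, eval_sample=name
        )
        out.append(mean_top_accuracy(amap, top_frac))
    return out[0], out[1]


def summarize_tiles(result: ExperimentResult) -> pd.DataFrame:
    """Recompute the tile summary from the stored accuracy maps."""
    return _tiles_frame(
        result.config, result.train_order, result.within_maps,
        result.across_maps, result.dice,
    )
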