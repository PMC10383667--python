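"""Synthetic expression studies with planted informative genes.

The generator emulates the structure of the bulk biopsy cohort the pipeline
is designed for — three diagnostic classes (control, ulcerative colitis,
Crohn's disease) in the cohort's observed proportions, ages on 19-82 years,
two sexes, seven biopsy regions in their observed frequencies — at a
configurable desk scale. A chosen number of genes carry a class-conditional
mean shift (in within-class standard deviation units) on one or both binary
contrasts; every other gene is class-independent noise, so ground truth for
any selection procedure is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .study import ExpressionStudy, REGIONS, StudyError
from .util import largest_remainder

__all__ = ["SimulationConfig", "GroundTruth", "generate_study", "write_fixture_bundle"]

# Cohort composition the generator mirrors by default: 2,490 biopsies of
# which 461 control / 872 UC / 1,157 CD; region counts 904 Rectum, 180 Left
# colon, 252 Right colon, 672 Ileum, 90 Transverse, 163 Sigmoid, 229 Cecum;
# 1,316 of 2,490 male; ages 19-82 averaging ~45.
_COHORT_CLASS_PROPS = (461 / 2490, 872 / 2490, 1157 / 2490)
_REGION_COUNTS = (904, 180, 252, 672, 90, 163, 229)
_MALE_FRACTION = 1316 / 2490
_AGE_MEAN, _AGE_SD, _AGE_MIN, _AGE_MAX = 44.9, 14.0, 19, 82

_TASKS = ("control_vs_ibd", "uc_vs_cd", "both")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``effect_size`` is the class-mean shift of a planted gene in units of the
    within-class standard deviation (``baseline_sd``). With
    ``informative_task="both"`` the planted genes are split evenly between
    the two contrasts and ``uc_cd_effect_size`` (default: ``effect_size``)
    sets the shift of the UC-vs-CD half.
    """

    n_samples: int = 300
    n_genes: int = 500
    class_proportions: tuple[float, float, float] = _COHORT_CLASS_PROPS
    n_informative: int = 25
    effect_size: float = 1.5
    informative_task: str = "control_vs_ibd"
    uc_cd_effect_size: float | None = None
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    distribution: str = "gaussian"  # or "lognormal"
    confound_region: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("need n_samples >= 2 and n_genes >= 1")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must lie in [0, n_genes]")
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != 3 or np.any(props < 0) or abs(props.sum() - 1) > 1e-9:
            raise ValueError("class_proportions must be 3 non-negatives summing to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.informative_task not in _TASKS:
            raise ValueError(f"informative_task must be one of {_TASKS}")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError("distribution must be 'gaussian' or 'lognormal'")


@dataclass
class GroundTruth:
    """What was planted: the informative genes and their class-conditional means."""

    informative_gene_ids: list[str]
    class_means: pd.DataFrame  # gene_id, contrast, mean_control, mean_uc, mean_cd
    labels: np.ndarray = field(repr=False)


def _class_counts(config: SimulationConfig) -> list[int]:
    counts = largest_remainder(config.class_proportions, config.n_samples)
    for prop, cnt, name in zip(config.class_proportions, counts, ("control", "UC", "CD")):
        if prop > 0 and cnt == 0:
            raise StudyError(
                f"class {name!r} has proportion {prop} but 0 samples after rounding; "
                "increase n_samples"
            )
    return counts


def generate_study(config: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate one study plus its ground truth, deterministically per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_genes

    counts = _class_counts(config)
    labels = np.repeat(np.array(["control", "UC", "CD"], dtype=object), counts)
    labels = labels[rng.permutation(n)]

    age = np.clip(
        np.rint(rng.normal(_AGE_MEAN, _AGE_SD, n)), _AGE_MIN, _AGE_MAX
    ).astype(int)
    sex = (rng.random(n) < _MALE_FRACTION).astype(int)

    region_props = np.asarray(_REGION_COUNTS, dtype=float)
    region_props /= region_props.sum()
    if config.confound_region:
        # deliberately tie region to class: IBD biopsies skew toward the ileum
        region = np.empty(n, dtype=object)
        skew = region_props.copy()
        skew[REGIONS.index("Ileum")] *= 3.0
        skew /= skew.sum()
        ibd = labels != "control"
        region[ibd] = rng.choice(REGIONS, size=int(ibd.sum()), p=skew)
        region[~ibd] = rng.choice(REGIONS, size=int((~ibd).sum()), p=region_props)
    else:
        region = rng.choice(REGIONS, size=n, p=region_props).astype(object)

    expr = rng.normal(config.baseline_mean, config.baseline_sd, size=(m, n))

    gene_ids = [f"G{i:05d}" for i in range(m)]
    sample_ids = [f"S{j:04d}" for j in range(n)]

    informative = np.sort(rng.choice(m, size=config.n_informative, replace=False))
    shift = config.effect_size * config.baseline_sd
    shift2 = (config.uc_cd_effect_size if config.uc_cd_effect_size is not None
              else config.effect_size) * config.baseline_sd

    records = []
    base = config.baseline_mean
    if config.informative_task == "both":
        half = len(informative) // 2
        groups = [(informative[:half], "control_vs_ibd", shift),
                  (informative[half:], "uc_vs_cd", shift2)]
    else:
        groups = [(informative, config.informative_task, shift)]
    for idx, contrast, delta in groups:
        if contrast == "control_vs_ibd":
            cols = labels != "control"
            means = (base, base + delta, base + delta)
        else:  # uc_vs_cd: shift CD only, so UC and control stay at baseline
            cols = labels == "CD"
            means = (base, base, base + delta)
        for k in idx:
            expr[k, cols] += delta
            records.append(
                dict(gene_id=gene_ids[k], contrast=contrast,
                     mean_control=means[0], mean_uc=means[1], mean_cd=means[2])
            )

    if config.distribution == "lognormal":
        expr = np.exp(expr * 0.25)  # damp the scale so values stay O(10)

    study = ExpressionStudy(
        gene_ids=gene_ids,
        expression=expr,
        labels=labels,
        age=age,
        sex=sex,
        region=region,
        sample_ids=sample_ids,
    )
    truth = GroundTruth(
        informative_gene_ids=[gene_ids[k] for k in informative],
        class_means=pd.DataFrame(
            records, columns=["gene_id", "contrast", "mean_control", "mean_uc", "mean_cd"]
        ),
        labels=labels.copy(),
    )
    return study, truth


def write_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a study and write study TSV + ground-truth CSV + config echo.

    Regenerating from the echoed config reproduces the study file
    byte-for-byte.
    """
    from .study import write_study  # local import to avoid cycles at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study, truth = generate_study(config)
    paths = {
        "study": out / "study.tsv",
        "ground_truth": out / "ground_truth.csv",
        "config": out / "config.yaml",
    }
    write_study(study, paths["study"])
    truth.class_means.to_csv(paths["ground_truth"], index=False)
    echo = asdict(config)
    echo["class_proportions"] = [float(p) for p in echo["class_proportions"]]
    with paths["config"].open("w", encoding="utf-8") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return paths


def load_config(path: str | Path) -> SimulationConfig:
    """Read back a config echoed by :func:`write_fixture_bundle`."""
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    raw["class_proportions"] = tuple(raw["class_proportions"])
    return SimulationConfig(**raw)
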