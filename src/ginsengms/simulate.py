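"""Synthetic LC-MS data with the statistical structure the pipeline assumes.

The original study data (31 training + 8 test ginseng batches from
three provinces, 69 aligned ginsenoside peaks) are not publicly
deposited, so this module generates feature tables and per-sample peak
lists that emulate the study design:

* three origin classes with a configurable number of samples each,
* log-normal peak areas (intensities in MS are positive and
  right-skewed; class effects act multiplicatively),
* a small planted set of origin-discriminative features, where each
  class shifts a disjoint third of the informative set so that every
  class is separable from both others,
* strong per-feature scale heterogeneity (peak areas of different
  compounds span orders of magnitude), which is what makes raw-area
  classification fragile and Z-scoring effective,
* sporadic missingness (a feature undetected in a sample is a 0), and
* per-occurrence m/z and RT jitter for exercising peak alignment.

Ground truth (informative feature indices, per-class shift patterns,
per-feature scales) is always returned alongside the data so recovery
can be tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ginsengms.features import FeatureTable, Peak, PeakList

__all__ = ["SyntheticSpec", "GroundTruth", "generate_feature_table", "generate_peak_lists"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic-data generator.

    Parameters
    ----------
    n_per_class : int or sequence of int
        Samples per origin class; a sequence gives per-class counts
        (the study itself was unbalanced: 19 JL, 4 LN, 8 HLJ).
    class_names : sequence of str
        Origin labels; default the three provinces.
    n_features : int
        Total number of aligned peaks.
    n_informative : int
        Planted origin-discriminative peaks (the study found six
        markers among 69 common peaks).
    effect_size : float
        Per-class mean shift of informative features, in log-intensity
        units (a shift of 1 is a factor e in area).
    class_effect_multipliers : sequence of float, optional
        Per-class multiplier on ``effect_size``; default all 1.
    log_mu, log_sigma : float
        Mean and sd of baseline log areas before per-feature scaling.
    scale_spread : float
        Per-feature scale heterogeneity: each feature's areas are
        multiplied by ``scale_spread ** u`` with ``u ~ U(-1/2, 1/2)``,
        so extreme features differ by a factor ``scale_spread``.
    missing_prob : float
        Independent probability that a feature is undetected (area 0)
        in a sample.
    mz_range, rt_range : (float, float)
        Da and minute intervals for consensus feature coordinates
        (defaults follow a 400-1700 Da scan over a ~32 min gradient).
    mz_jitter_ppm, rt_jitter_min : float
        Half-width of the uniform measurement jitter applied to each
        detected occurrence in :func:`generate_peak_lists`.
    seed : int
        RNG seed; the same spec and seed give byte-identical output.
    """

    n_per_class: int | tuple[int, ...] = 10
    class_names: tuple[str, ...] = ("JL", "LN", "HLJ")
    n_features: int = 69
    n_informative: int = 6
    effect_size: float = 1.5
    class_effect_multipliers: tuple[float, ...] | None = None
    log_mu: float = 11.0
    log_sigma: float = 0.3
    scale_spread: float = 1e3
    missing_prob: float = 0.02
    mz_range: tuple[float, float] = (400.0, 1700.0)
    rt_range: tuple[float, float] = (1.0, 32.0)
    mz_jitter_ppm: float = 5.0
    rt_jitter_min: float = 0.05
    reference_coordinates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_class, Sequence) and not isinstance(self.n_per_class, str):
            object.__setattr__(self, "n_per_class", tuple(int(v) for v in self.n_per_class))
        object.__setattr__(self, "class_names", tuple(self.class_names))
        if self.class_effect_multipliers is not None:
            object.__setattr__(
                self, "class_effect_multipliers", tuple(self.class_effect_multipliers)
            )
        self.validate()

    def validate(self) -> None:
        counts = self.counts_per_class
        if any(c < 1 for c in counts):
            raise ValueError("n_per_class: every class needs at least one sample")
        if len(self.class_names) < 2:
            raise ValueError("class_names: at least two origin classes required")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names: labels must be distinct")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not (0 <= self.n_informative <= self.n_features):
            raise ValueError("n_informative must satisfy 0 <= n_informative <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.missing_prob <= 1):
            raise ValueError("missing_prob must be in [0, 1]")
        if self.log_sigma < 0:
            raise ValueError("log_sigma must be >= 0")
        if self.scale_spread < 1:
            raise ValueError("scale_spread must be >= 1")
        if self.mz_jitter_ppm < 0 or self.rt_jitter_min < 0:
            raise ValueError("jitter parameters must be >= 0")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must be an increasing interval")
        if not self.rt_range[0] < self.rt_range[1]:
            raise ValueError("rt_range must be an increasing interval")
        if self.class_effect_multipliers is not None and len(
            self.class_effect_multipliers
        ) != len(self.class_names):
            raise ValueError(
                "class_effect_multipliers must have one entry per class"
            )

    @property
    def counts_per_class(self) -> tuple[int, ...]:
        if isinstance(self.n_per_class, tuple):
            if len(self.n_per_class) != len(self.class_names):
                raise ValueError("n_per_class tuple must match class_names length")
            return self.n_per_class
        return tuple(int(self.n_per_class) for _ in self.class_names)

    @property
    def n_samples(self) -> int:
        return sum(self.counts_per_class)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``class_shift[c, j]`` is the additive log-intensity shift applied
    to feature ``j`` in class ``c``; informative features are exactly
    the columns with a nonzero shift somewhere.
    """

    informative: np.ndarray
    class_shift: np.ndarray
    feature_scale: np.ndarray
    feature_mz: np.ndarray
    feature_rt: np.ndarray
    labels: list[str] = field(default_factory=list)


def _consensus_coordinates(spec: SyntheticSpec, rng: np.random.Generator):
    if spec.reference_coordinates:
        # borrow measured (m/z, RT) pairs of real ginsenosides so
        # synthetic features are annotatable against the packaged DB
        from ginsengms.annotation import load_reference_db

        db = load_reference_db()
        # keep only mutually resolvable coordinates: a pair both within
        # 20 ppm and within 0.4 min would scramble during alignment
        order = rng.permutation(len(db))
        chosen: list[int] = []
        for i in order:
            ok = all(
                abs(db[i].mass_ion_mz - db[j].mass_ion_mz) / db[j].mass_ion_mz * 1e6
                > 20.0
                or abs(db[i].rt - db[j].rt) > 0.4
                for j in chosen
            )
            if ok:
                chosen.append(i)
            if len(chosen) == spec.n_features:
                break
        mz = np.array([db[i].mass_ion_mz for i in chosen])
        rt = np.array([db[i].rt for i in chosen])
        extra = spec.n_features - len(chosen)
        if extra > 0:
            mz = np.concatenate([mz, rng.uniform(*spec.mz_range, size=extra)])
            rt = np.concatenate([rt, rng.uniform(*spec.rt_range, size=extra)])
    else:
        mz = np.sort(rng.uniform(*spec.mz_range, size=spec.n_features))
        rt = rng.uniform(*spec.rt_range, size=spec.n_features)
    # order features by (rt, mz): the convention of aligned LC-MS tables
    order = np.lexsort((mz, rt))
    return mz[order], rt[order]


def _class_shifts(spec: SyntheticSpec, rng: np.random.Generator, informative: np.ndarray):
    """Disjoint thirds of the informative set are shifted per class."""
    n_classes = len(spec.class_names)
    mult = spec.class_effect_multipliers or tuple(1.0 for _ in spec.class_names)
    shift = np.zeros((n_classes, spec.n_features))
    groups = np.array_split(informative, n_classes)
    for c, grp in enumerate(groups):
        shift[c, grp] = spec.effect_size * mult[c]
    return shift


def generate_feature_table(
    spec: SyntheticSpec, sample_seed: int | None = None
) -> tuple[FeatureTable, GroundTruth]:
    """Draw one labelled feature table (and its ground truth) from ``spec``.

    Areas are ``exp(log_mu + class shift + N(0, log_sigma)) * scale_j``
    with independent Bernoulli(``missing_prob``) dropout to zero.

    The *structure* of the dataset (feature coordinates, per-feature
    scales, which features are informative and how each class shifts
    them) is drawn from ``spec.seed`` alone; the per-sample draws come
    from ``sample_seed`` (default: also ``spec.seed``).  Passing a new
    ``sample_seed`` therefore yields held-out samples from the *same*
    population — the natural way to simulate external test batches.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    mz, rt = _consensus_coordinates(spec, rng)

    informative = np.sort(
        rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    )
    shift = _class_shifts(spec, rng, informative)
    log_scale = np.log(spec.scale_spread) * rng.uniform(-0.5, 0.5, size=spec.n_features)

    if sample_seed is None:
        sample_seed = spec.seed
    srng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7, sample_seed]))
    counts = spec.counts_per_class
    labels: list[str] = []
    rows = []
    for c, name in enumerate(spec.class_names):
        loglatent = spec.log_mu + shift[c] + srng.normal(
            0.0, spec.log_sigma, size=(counts[c], spec.n_features)
        )
        rows.append(loglatent)
        labels.extend([name] * counts[c])
    areas = np.exp(np.vstack(rows) + log_scale)
    detected = srng.random(areas.shape) >= spec.missing_prob
    areas = areas * detected

    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    table = FeatureTable(
        sample_ids=sample_ids,
        areas=areas,
        feature_mz=mz,
        feature_rt=rt,
        origins=labels,
    )
    truth = GroundTruth(
        informative=informative,
        class_shift=shift,
        feature_scale=np.exp(log_scale),
        feature_mz=mz,
        feature_rt=rt,
        labels=labels,
    )
    return table, truth


def generate_peak_lists(
    spec: SyntheticSpec, sample_seed: int | None = None
) -> tuple[list[PeakList], FeatureTable, GroundTruth]:
    """Per-sample peak lists derived from :func:`generate_feature_table`.

    Each detected occurrence of a feature gets the feature's consensus
    m/z jittered by up to ``mz_jitter_ppm`` (uniform, relative) and its
    consensus RT jittered by up to ``rt_jitter_min``; undetected
    entries are simply absent from the sample's list.  The source
    table and ground truth are returned so alignment can be checked
    against them.  ``sample_seed`` has the same meaning as in
    :func:`generate_feature_table`.
    """
    table, truth = generate_feature_table(spec, sample_seed=sample_seed)
    if sample_seed is None:
        sample_seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, sample_seed]))

    # two features are only confusable if they are close in BOTH m/z
    # and RT; isomers sharing an m/z but chromatographically separated
    # are fine
    mzv, rtv = table.feature_mz, table.feature_rt
    if len(mzv) > 1:
        dmz_ppm = np.abs(mzv[:, None] - mzv[None, :]) / mzv[None, :] * 1e6
        drt = np.abs(rtv[:, None] - rtv[None, :])
        close = (dmz_ppm <= 2 * spec.mz_jitter_ppm) & (drt <= 2 * spec.rt_jitter_min)
        np.fill_diagonal(close, False)
        if close.any():
            n_pairs = int(close.sum() // 2)
            warnings.warn(
                f"{n_pairs} feature pair(s) are within twice the m/z and RT "
                "jitter of each other; alignment may be ambiguous",
                stacklevel=2,
            )
            logger.warning("%d confusable feature pairs under current jitter", n_pairs)

    lists: list[PeakList] = []
    for i, sid in enumerate(table.sample_ids):
        peaks = []
        for j in range(table.n_features):
            area = table.areas[i, j]
            if area <= 0:
                continue
            mz = table.feature_mz[j] * (
                1.0 + rng.uniform(-spec.mz_jitter_ppm, spec.mz_jitter_ppm) * 1e-6
            )
            rt = max(
                0.0,
                table.feature_rt[j]
                + rng.uniform(-spec.rt_jitter_min, spec.rt_jitter_min),
            )
            peaks.append(
                Peak(
                    mz=mz,
                    rt=rt,
                    area=area,
                    charge=1,
                    quality_score=float(rng.uniform(61.0, 100.0)),
                )
            )
        origin = table.origins[i] if table.origins is not None else None
        lists.append(PeakList(sample_id=sid, peaks=peaks, origin=origin))
    return lists, table, truth
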