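"""Synthetic binary metabolome fixtures.

Real repository-scale inputs are enormous (tens of thousands of samples and
features) and live behind community repositories; the generators here emit
small matrices with the same statistical structure, so every operation in the
package is exercisable offline:

* ingredient *libraries* — binary columns with controlled support size and
  pairwise support overlap;
* *complex* samples — unions of a few ingredient supports, with independent
  Bernoulli dropout (1→0) and spurious-detection (0→1) noise, mirroring the
  union assumption plus measurement noise;
* phenotype *cohorts* — imbalanced class structure, per-class signal
  features, and optionally a protocol confounder: features present if and
  only if a sample came from one source dataset, emulating an internal
  standard spiked in under a single acquisition protocol.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureMatrix, PhenotypeTable


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated fixture."""

    true_ingredients: list[str] = field(default_factory=list)
    class_signal_features: dict[str, list[str]] = field(default_factory=dict)
    confounder_features: list[str] = field(default_factory=list)
    generator_params: dict = field(default_factory=dict)


def make_library(
    n_features: int,
    n_ingredients: int,
    support_size: int,
    overlap: float = 0.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Reference library of ingredient profiles with controlled overlap.

    Each ingredient column carries exactly ``support_size`` ones.  A shared
    pool of ``round(overlap * support_size)`` features is present in every
    ingredient; the remaining features of each support are private
    (pairwise-disjoint), so any two supports share exactly the pool —
    ``overlap = 0`` gives fully disjoint supports.  Feature positions are
    shuffled so supports are not contiguous blocks.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    shared = int(round(overlap * support_size))
    private = support_size - shared
    needed = shared + private * n_ingredients
    if needed > n_features:
        raise ValueError(
            f"infeasible: {n_ingredients} ingredients x {private} private features "
            f"+ {shared} shared need {needed} > {n_features} features"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_features)
    values = np.zeros((n_features, n_ingredients), dtype=np.int8)
    pool = perm[:shared]
    for j in range(n_ingredients):
        block = perm[shared + j * private : shared + (j + 1) * private]
        values[pool, j] = 1
        values[block, j] = 1
    feature_ids = [f"f{i:05d}" for i in range(n_features)]
    ingredient_ids = [f"ing{j:03d}" for j in range(n_ingredients)]
    return FeatureMatrix(values, feature_ids, ingredient_ids)


def make_complex(
    library: FeatureMatrix,
    k: int,
    dropout: float = 0.0,
    spurious: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """One complex sample: the union of ``k`` ingredient supports, plus noise.

    Each 1 of the union is flipped to 0 with probability ``dropout`` (a real
    molecule missed by acquisition) and each 0 to 1 with probability
    ``spurious`` (a spurious detection).
    """
    if k > library.n_samples:
        raise ValueError(f"k={k} exceeds the {library.n_samples} library columns")
    if not (0 <= dropout < 1 and 0 <= spurious < 1):
        raise ValueError("noise rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(library.n_samples, size=k, replace=False).tolist())
    union = (library.values[:, chosen].sum(axis=1) > 0).astype(np.int8)
    c = union.copy()
    if dropout:
        ones = np.flatnonzero(union == 1)
        c[ones[rng.random(ones.size) < dropout]] = 0
    if spurious:
        zeros = np.flatnonzero(union == 0)
        c[zeros[rng.random(zeros.size) < spurious]] = 1
    truth = SyntheticTruth(
        true_ingredients=[library.sample_ids[j] for j in chosen],
        generator_params={
            "k": k, "dropout": dropout, "spurious": spurious, "seed": seed,
        },
    )
    return c, truth


def make_cohort(
    n_per_class: dict[str, int],
    n_features: int = 200,
    signal_per_class: int = 8,
    signal_penetrance: float = 0.9,
    background_rate: float = 0.05,
    confound: tuple[str, str, int] | None = None,
    shift_confounder_to: str | None = None,
    seed: int = 0,
) -> tuple[FeatureMatrix, PhenotypeTable, SyntheticTruth]:
    """Phenotype cohort with class signal and an optional protocol confounder.

    Background features fire everywhere at ``background_rate``.  Each class
    owns ``signal_per_class`` signal features, present at
    ``signal_penetrance`` in-class and ``background_rate`` out-of-class (the
    real biology).  ``confound = (class_label, dataset_id, n_features)``
    dedicates that many extra features that are present **iff** the sample
    belongs to ``dataset_id`` — and in training-style generation that dataset
    holds exactly the samples of ``class_label``, so the confounder is
    perfectly class-correlated without being biology.  Passing
    ``shift_confounder_to`` generates a *shifted* cohort instead, in which
    the confounded dataset (and its spiked standard) covers a different
    class — the scenario where a protocol artifact misleads a trained model.

    The default cohort proportions used throughout the package keep > 90 %
    of samples in the majority class, mirroring repository-scale phenotype
    imbalance.
    """
    if any(n < 1 for n in n_per_class.values()):
        raise ValueError("class sizes must be >= 1")
    if not (0 <= signal_penetrance <= 1 and 0 <= background_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    classes = sorted(n_per_class)
    n_conf = confound[2] if confound else 0
    total_special = signal_per_class * len(classes) + n_conf
    if total_special > n_features:
        raise ValueError("not enough features for signals and confounders")

    feature_ids = [f"f{i:05d}" for i in range(n_features)]
    signal_of: dict[str, list[str]] = {}
    cursor = 0
    for cls_label in classes:
        signal_of[cls_label] = feature_ids[cursor : cursor + signal_per_class]
        cursor += signal_per_class
    conf_features = feature_ids[cursor : cursor + n_conf]
    cursor += n_conf

    sample_ids, labels, dataset_ids = [], [], []
    for cls_label in classes:
        for i in range(n_per_class[cls_label]):
            sample_ids.append(f"s_{cls_label}_{i:04d}")
            labels.append(cls_label)
            dataset_ids.append(f"DS_{cls_label}")
    n = len(sample_ids)

    values = (rng.random((n_features, n)) < background_rate).astype(np.int8)
    idx_of = {f: i for i, f in enumerate(feature_ids)}
    labels_arr = np.asarray(labels)
    for cls_label in classes:
        cols = np.flatnonzero(labels_arr == cls_label)
        for f in signal_of[cls_label]:
            values[idx_of[f], cols] = (
                rng.random(cols.size) < signal_penetrance
            ).astype(np.int8)

    standards: dict[str, set[str]] = {}
    if confound:
        conf_class, conf_dataset, _ = confound
        if conf_class not in classes:
            raise ValueError(f"confounded class {conf_class!r} not in cohort")
        carrier = shift_confounder_to if shift_confounder_to is not None else conf_class
        if carrier not in classes:
            raise ValueError(f"shift target class {carrier!r} not in cohort")
        carrier_cols = np.flatnonzero(labels_arr == carrier)
        for f in conf_features:
            values[idx_of[f], :] = 0
            values[idx_of[f], carrier_cols] = 1
        for j in carrier_cols:
            dataset_ids[j] = conf_dataset
        standards[conf_dataset] = set(conf_features)

    meta = PhenotypeTable(
        pd.DataFrame(
            {"label": labels, "dataset_id": dataset_ids},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        standards,
    )
    truth = SyntheticTruth(
        class_signal_features={c: list(signal_of[c]) for c in classes},
        confounder_features=list(conf_features),
        generator_params={
            "n_per_class": dict(n_per_class),
            "n_features": n_features,
            "signal_per_class": signal_per_class,
            "signal_penetrance": signal_penetrance,
            "background_rate": background_rate,
            "confound": list(confound) if confound else None,
            "shift_confounder_to": shift_confounder_to,
            "seed": seed,
        },
    )
    return FeatureMatrix(values, feature_ids, sample_ids), meta, truth
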