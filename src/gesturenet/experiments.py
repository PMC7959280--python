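"""Canned simulation scenarios and end-to-end benchmark runs.

These bundle the full pipeline — generate a labelled synthetic dataset,
extract the 60-feature table, cross-validate the classifiers — into single
calls used by the examples, the acceptance script and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .classify import ClassifierSpec, CVReport, cross_validate
from .communities import CommunityConfig, detect_communities
from .connectivity import ConnectivityConfig, build_tensor
from .montage import Montage, simulated_montage
from .netfeatures import FeatureConfig
from .pipeline import extract_feature_table
from .recording import (DOMINANT_GESTURES, NONDOMINANT_GESTURES,
                        extract_epochs)
from .simulate import (ClassSpec, SimulationConfig, cortex_group_specs,
                       generate_dataset, planted_partition)


def gesture_simulation_config(hand: str = "non-dominant",
                              n_per_class: int = 60,
                              coupling: float = 0.9,
                              power_step: float = 0.15,
                              montage: Montage | None = None,
                              imbalanced: bool = False,
                              seed: int = 0) -> tuple[SimulationConfig,
                                                      Montage]:
    """A labelled multi-class scenario over the full gesture vocabulary.

    ``hand='dominant'`` uses the 8-gesture dominant-hand label set,
    ``'non-dominant'`` the 6-gesture set. With ``imbalanced`` the class
    counts are spread geometrically around ``n_per_class`` (mimicking the
    uneven gesture inventories of real surgeries); otherwise balanced.
    With ``coupling=0`` and ``power_step=0`` the classes carry no planted
    effect at all — the null scenario.
    """
    montage = montage or simulated_montage(8, 6, 4)
    gestures = (DOMINANT_GESTURES if hand == "dominant"
                else NONDOMINANT_GESTURES)
    labels_hands = [(g, hand) for g in gestures]
    if imbalanced:
        ratios = np.geomspace(0.5, 2.0, len(gestures))
        counts = [max(2, int(round(n_per_class * r))) for r in ratios]
    else:
        counts = [n_per_class] * len(gestures)
    specs = cortex_group_specs(montage, labels_hands, counts,
                               coupling=coupling, power_step=power_step)
    if coupling == 0.0:
        # null scenario: drop the group structure entirely
        specs = [ClassSpec(label=s.label, hand=s.hand, count=s.count,
                           groups=[], power_gain=s.power_gain)
                 for s in specs]
    cfg = SimulationConfig(n_channels=montage.n_channels, classes=specs,
                           duration_range_s=(2.0, 3.5), seed=seed)
    return cfg, montage


@dataclass
class BenchmarkResult:
    features: pd.DataFrame
    reports: dict[str, CVReport]
    n_epochs: int
    n_classes: int

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


def run_gesture_benchmark(sim_config: SimulationConfig, montage: Montage,
                          classifiers: tuple[str, ...] = ("ET",),
                          comm_config: CommunityConfig | None = None,
                          n_selected: int | None = None,
                          seed: int = 0) -> BenchmarkResult:
    """Generate -> extract 60 features -> stratified 10-fold CV."""
    rec, ann = generate_dataset(sim_config)
    epochs = extract_epochs(rec, ann)
    features = extract_feature_table(
        epochs, montage, comm_config=comm_config or CommunityConfig(),
        seed=seed)
    reports = {name: cross_validate(features, ClassifierSpec(name=name),
                                    n_selected=n_selected, seed=seed)
               for name in classifiers}
    return BenchmarkResult(features=features, reports=reports,
                           n_epochs=len(features),
                           n_classes=features["label"].nunique())


def null_accuracy_summary(n_datasets: int = 3, n_per_class: int = 60,
                          hand: str = "non-dominant",
                          comm_config: CommunityConfig | None = None,
                          seed: int = 0) -> tuple[float, float]:
    """Mean ET accuracy and its standard error on null-effect data.

    Accuracy is estimated on ``n_datasets`` independently seeded datasets
    with no planted coupling or power differences; the SE is taken across
    datasets. Per-fold SEs within one dataset understate the sampling
    variability of a cross-validated mean (folds share the dataset), so the
    across-dataset SE is the honest scale for a chance-level check.
    """
    means = []
    for k in range(n_datasets):
        cfg, montage = gesture_simulation_config(
            hand=hand, n_per_class=n_per_class, coupling=0.0,
            power_step=0.0, seed=seed + 17 * k)
        res = run_gesture_benchmark(
            cfg, montage, classifiers=("ET",),
            comm_config=comm_config or CommunityConfig(repetitions=10,
                                                       null_permutations=10),
            seed=seed + 17 * k)
        means.append(float(np.mean(res.reports["ET"].fold_accuracies)))
    arr = np.asarray(means)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))


def planted_recovery_rate(n_trials: int = 20, coupling: float = 0.9,
                          n_channels: int = 8, group_size: int = 4,
                          repetitions: int = 20, seed: int = 0) -> float:
    """Fraction of seeded trials in which consensus community detection
    recovers the planted channel groups exactly (adjusted Rand index 1)."""
    spec = ClassSpec(label="Suturing", hand="dominant", count=1,
                     groups=[list(range(group_size)),
                             list(range(group_size, 2 * group_size))],
                     coupling=coupling)
    hits = 0
    for trial in range(n_trials):
        cfg = SimulationConfig(n_channels=n_channels, classes=[spec],
                               seed=seed + 1000 * trial,
                               duration_range_s=(4.0, 4.0))
        rec, ann = generate_dataset(cfg)
        ep = extract_epochs(rec, ann)[0]
        tensor = build_tensor(ep)
        ccfg = CommunityConfig(repetitions=repetitions,
                               null_permutations=repetitions,
                               seed=seed + 1000 * trial)
        cons, _, _ = detect_communities(tensor, ccfg)
        truth = planted_partition(cfg, "Suturing").assignments[:, 0]
        hits += adjusted_rand_score(truth, cons.assignments[:, 0]) == 1.0
    return hits / n_trials
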