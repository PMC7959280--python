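"""End-to-end feature extraction: epochs -> coherence tensors ->
community structure -> 60-feature table ready for classification."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .communities import CommunityConfig, detect_communities
from .connectivity import ConnectivityConfig, build_tensor
from .montage import Montage
from .netfeatures import FeatureConfig, assemble_features
from .recording import GestureEpoch


def extract_feature_table(epochs: list[GestureEpoch], montage: Montage,
                          conn_config: ConnectivityConfig | None = None,
                          comm_config: CommunityConfig | None = None,
                          feat_config: FeatureConfig | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """One feature row per gesture epoch.

    Each epoch gets its own community-detection substream derived from the
    master seed, so the table is reproducible and epoch order does not leak
    randomness between epochs.
    """
    conn_config = conn_config or ConnectivityConfig()
    comm_config = comm_config or CommunityConfig()
    feat_config = feat_config or FeatureConfig()
    seeds = np.random.SeedSequence(seed).generate_state(max(len(epochs), 1))
    rows = []
    for epoch, sub in zip(epochs, seeds):
        tensor = build_tensor(epoch, conn_config)
        cfg = replace(comm_config, seed=int(sub % (2 ** 31)))
        partition, mam, _ = detect_communities(tensor, cfg)
        feats = assemble_features(epoch, tensor, partition, mam, montage,
                                  feat_config)
        feats["label"] = epoch.label
        feats["hand"] = epoch.hand
        feats["subject"] = epoch.subject
        rows.append(feats)
    return pd.DataFrame(rows)
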