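"""End-to-end convenience drivers chaining the pipeline stages.

detect -> cluster within trajectory -> filter rare -> merge superclusters.
Thin glue used by the command-line interface, the test-suite and the
reproduction script; all science lives in the stage modules.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .io_formats import Ensemble
from .tunnel_clustering import (
    ClusterParams,
    ReplicateClusters,
    SuperCluster,
    cluster_within_trajectory,
    filter_rare,
    merge_superclusters,
)
from .tunnel_detection import (
    DetectionParams,
    StartPointSpec,
    detect_ensemble,
)

logger = logging.getLogger(__name__)

__all__ = ["cluster_ensemble", "analyze_ensembles"]


def cluster_ensemble(
    ensemble: Ensemble,
    start: np.ndarray | StartPointSpec,
    det_params: DetectionParams = DetectionParams(),
    clus_params: ClusterParams = ClusterParams(),
    batch_size: int | None = None,
) -> ReplicateClusters:
    """Detect and cluster tunnels of one replicate, dropping rare clusters."""
    profiles = detect_ensemble(ensemble, start, det_params, batch_size=batch_size)
    if profiles:
        clusters = cluster_within_trajectory(profiles, ensemble.n_frames, clus_params)
        clusters = filter_rare(clusters, ensemble.n_frames, clus_params)
    else:
        logger.warning("replicate %s: no tunnels detected", ensemble.replicate_id)
        clusters = []
    return ReplicateClusters(
        replicate_id=ensemble.replicate_id,
        condition=ensemble.condition,
        n_frames=ensemble.n_frames,
        frame_spacing=ensemble.frame_spacing,
        clusters=clusters,
    )


def analyze_ensembles(
    ensembles: Sequence[Ensemble],
    start: np.ndarray | StartPointSpec,
    det_params: DetectionParams = DetectionParams(),
    clus_params: ClusterParams = ClusterParams(),
    batch_size: int | None = None,
) -> list[SuperCluster]:
    """Full pipeline over all replicates of a study."""
    replicates = [
        cluster_ensemble(e, start, det_params, clus_params, batch_size=batch_size)
        for e in ensembles
    ]
    return merge_superclusters(replicates, clus_params)
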