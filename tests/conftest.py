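"""Shared fixtures: seeded synthetic datasets and recovery helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from hyaloquant import (
    assign_puncta_to_segments,
    build_vessel_mask,
    classify_cells,
    classify_segments,
    detect_tunel_puncta,
    segment_nuclei,
    skeletonize_graph,
)
from hyaloquant.synthetic import (
    CountsSimSpec,
    ImageSimSpec,
    generate_counts,
    generate_flatmount,
)


@pytest.fixture(scope="session")
def noisefree_flatmount():
    return generate_flatmount(ImageSimSpec(seed=0))


@pytest.fixture(scope="session")
def noisy_flatmount():
    return generate_flatmount(ImageSimSpec(seed=0).with_noise(0.1))


def run_imaging_pipeline(image):
    """Convenience: mask → nuclei → puncta → graph → calls for one image."""
    mask = build_vessel_mask(image, "CD31")
    nuclei = classify_cells(segment_nuclei(image), mask)
    puncta = detect_tunel_puncta(image, "TUNEL", mask)
    graph = skeletonize_graph(mask)
    puncta = assign_puncta_to_segments(graph, puncta)
    calls = classify_segments(graph, puncta, image.channel("CD31"))
    return mask, nuclei, puncta, graph, calls


@pytest.fixture(scope="session")
def noisefree_pipeline(noisefree_flatmount):
    image, gt = noisefree_flatmount
    return run_imaging_pipeline(image) + (gt,)


@pytest.fixture(scope="session")
def counts_dataset():
    return generate_counts(CountsSimSpec(seed=0))


def class_accuracy(nuclei, gt_nuclei) -> float:
    """Fraction of detected nuclei matching the nearest planted nucleus class."""
    tree = cKDTree(gt_nuclei[["row", "col"]].to_numpy())
    hits = 0
    for n in nuclei:
        d, i = tree.query(n.centroid)
        hits += d < 8 and gt_nuclei["cell_class"].iloc[i] == n.cell_class
    return hits / max(len(nuclei), 1)


def regression_f1(graph, calls, gt) -> float:
    """F1 of regressing-segment calls against planted regressing segments.

    Each planted cluster is matched to the skeleton edge nearest its
    centroid; precision counts unmatched regressing calls as false
    positives.
    """
    reg_ids = {c.edge_id for c in calls if c.status == "regressing"}
    tp, matched = 0, set()
    for gi in gt.regressing_edges:
        cluster = gt.puncta[gt.puncta.edge_index == gi][["row", "col"]].to_numpy()
        center = cluster.mean(axis=0)
        best = min(
            graph.edges,
            key=lambda e: np.min(np.hypot(*(e.path.astype(float) - center).T)),
        ).edge_id
        if best in reg_ids and best not in matched:
            tp += 1
            matched.add(best)
    fp = len(reg_ids) - len(matched)
    fn = len(gt.regressing_edges) - tp
    return 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 1.0
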