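"""Run orchestration and group reporting.

Assembles the stage outputs into per-animal tables, expresses group values
as percentages of the control-group mean, and runs the full flatmount +
topology (+ optional retina, + optional SORT-seq) pipeline from a single
configuration with reproducible, parameter-hashed outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import io as hqio
from .image_quant import (
    build_vessel_mask,
    classify_cells,
    detect_tunel_puncta,
    quantify_membrane_marker,
    quantify_nuclear_marker,
    segment_nuclei,
)
from .retina_metrics import retina_metrics
from .types import FlatmountImage, QuantParams
from .vessel_topology import (
    TopologyParams,
    assign_puncta_to_segments,
    classify_segments,
    flatmount_regression_summary,
    skeletonize_graph,
)

logger = logging.getLogger("hyaloquant")

__all__ = ["RunConfig", "percent_of_control", "run_pipeline"]


def percent_of_control(
    values: Sequence[float],
    groups: Sequence[str],
    control_group: str,
    animals: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Express per-animal values as percentages of the control-group mean.

    Each biological-replicate value is divided by the mean of the control
    group and multiplied by 100, so the control group averages 100% by
    construction.
    """
    df = pd.DataFrame({"value": list(values), "group": list(groups)})
    df["animal"] = list(animals) if animals is not None else np.arange(len(df))
    ctrl = df.loc[df["group"] == control_group, "value"]
    if len(ctrl) == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    ctrl_mean = ctrl.mean()
    if ctrl_mean == 0:
        raise ValueError("control-group mean is zero; percent of control undefined")
    df["percent_of_control"] = 100.0 * df["value"] / ctrl_mean
    return df


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str
    image: Any = None  # FlatmountImage or TIFF path
    channel_config: Any = None  # dict or YAML path (required for a TIFF path)
    cd31_channel: str = "CD31"
    dapi_channel: str = "DAPI"
    tunel_channel: str = "TUNEL"
    collagen_channel: str | None = None
    nuclear_markers: tuple[str, ...] = ()
    membrane_markers: tuple[str, ...] = ()
    quant_params: QuantParams = field(default_factory=QuantParams)
    topology_params: TopologyParams = field(default_factory=TopologyParams)
    seed: int = 0
    log_level: str = "INFO"

    def parameter_hash(self) -> str:
        payload = {
            "quant": asdict(self.quant_params),
            "topology": asdict(self.topology_params),
            "channels": {
                "cd31": self.cd31_channel,
                "dapi": self.dapi_channel,
                "tunel": self.tunel_channel,
                "collagen": self.collagen_channel,
                "nuclear_markers": list(self.nuclear_markers),
                "membrane_markers": list(self.membrane_markers),
            },
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the imaging stages in dependency order and write all tables.

    Every output carries the parameter hash, package version and seed.
    A stage failure aborts with the failing stage named; tables written by
    earlier stages are retained.
    """
    from . import __version__

    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "parameter_hash": config.parameter_hash(),
        "version": __version__,
        "seed": config.seed,
    }
    results: dict = {"provenance": provenance}

    image = config.image
    if image is not None and not isinstance(image, FlatmountImage):
        image = hqio.read_flatmount(image, config.channel_config)
    if image is None:
        hqio.write_json(provenance, out / "provenance.json")
        return results

    stage = "vessel_mask"
    try:
        mask = build_vessel_mask(image, config.cd31_channel, config.quant_params)
        stage = "nuclei"
        nuclei = segment_nuclei(image, config.dapi_channel, config.quant_params)
        nuclei = classify_cells(nuclei, mask, config.quant_params)
        stage = "markers"
        marker_summaries = {}
        for marker in config.nuclear_markers:
            _, summary = quantify_nuclear_marker(
                image, marker, nuclei, mask, config.quant_params
            )
            marker_summaries[marker] = {"statistic": "median_integrated", "value": summary}
        for marker in config.membrane_markers:
            marker_summaries[marker] = {
                "statistic": "mean_corrected",
                "value": quantify_membrane_marker(image, marker, mask, config.quant_params),
            }
        stage = "tunel"
        puncta = detect_tunel_puncta(image, config.tunel_channel, mask, config.quant_params)
        stage = "topology"
        graph = skeletonize_graph(mask, config.topology_params)
        puncta = assign_puncta_to_segments(graph, puncta, config.topology_params)
        calls = classify_segments(
            graph, puncta, image.channel(config.cd31_channel), config.topology_params
        )
        summary = flatmount_regression_summary(calls, puncta)
        stage = "retina"
        if config.collagen_channel is not None:
            collagen_mask = build_vessel_mask(
                image, config.collagen_channel, config.quant_params
            )
            results["retina_metrics"] = retina_metrics(collagen_mask)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    nuc_df = hqio.nuclei_table(nuclei)
    pun_df = hqio.puncta_table(puncta)
    seg_df = hqio.segment_table(calls)
    for df in (nuc_df, pun_df, seg_df):
        df["parameter_hash"] = provenance["parameter_hash"]
        df["seed"] = config.seed
    nuc_df.to_csv(out / "nuclei.csv", index=False)
    pun_df.to_csv(out / "puncta.csv", index=False)
    seg_df.to_csv(out / "segments.csv", index=False)
    hqio.write_json({**summary, **provenance}, out / "regression_summary.json")
    hqio.write_json(
        {"markers": marker_summaries, **provenance}, out / "marker_summaries.json"
    )
    if "retina_metrics" in results:
        m = results["retina_metrics"]
        hqio.write_json(
            {
                "vascular_area_um2": m.vascular_area_um2,
                "radial_expansion_um": m.radial_expansion_um,
                "density": m.density,
                **provenance,
            },
            out / "retina_metrics.json",
        )
    results.update(
        {
            "nuclei": nuc_df,
            "puncta": pun_df,
            "segments": seg_df,
            "regression_summary": summary,
            "marker_summaries": marker_summaries,
            "graph": graph,
        }
    )
    logger.info("pipeline complete: %d nuclei, %d puncta, %d segments",
                len(nuc_df), len(pun_df), len(seg_df))
    return results
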