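"""End-to-end processing of simulated (or stored) cores.

Glues the stages together: preprocess a channel stack, build the tissue
mask, extract CD34+ vessels with morphometry, call marker phenotypes,
and optionally transfer ground-truth labels onto recovered vessels for
classifier training and recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vesselphen.phenotyping import (
    CoreRecord,
    PhenotypingConfig,
    VesselObject,
    assign_marker_flags,
    build_tissue_mask,
    compute_core_areas,
    extract_vessels,
)
from vesselphen.preprocess import ChannelStack, QCRules, preprocess_stack, qc_core
from vesselphen.simulate.core import GroundTruth, ImageSimConfig, generate_core_image


@dataclass
class PreprocessConfig:
    filter_size: int = 9
    se_radius: float = 2.0


def process_core(
    stack: ChannelStack,
    case_id: str = "",
    pre: PreprocessConfig | None = None,
    pheno: PhenotypingConfig | None = None,
    qc_rules: QCRules | None = None,
) -> CoreRecord:
    """Run the full image stage on one core and return its record."""
    pre = pre or PreprocessConfig()
    pheno = pheno or PhenotypingConfig()
    qc = qc_core(stack, qc_rules)
    masks = preprocess_stack(
        stack, filter_size=pre.filter_size, se_radius=pre.se_radius
    )
    tissue = build_tissue_mask(masks, pheno.tissue_closing_radius_px)
    core_mm2, epi_mm2, stromal_mm2 = compute_core_areas(
        tissue, masks["KRT"].data, stack.pixel_size
    )
    vessels = extract_vessels(
        masks["CD34"], pheno, core_id=stack.core_id, pixel_size_um=stack.pixel_size
    )
    for v in vessels:
        assign_marker_flags(v, masks, pheno)
    return CoreRecord(
        core_id=stack.core_id,
        case_id=case_id,
        core_area_mm2=core_mm2,
        epithelial_area_mm2=epi_mm2,
        stromal_area_mm2=stromal_mm2,
        vessels=vessels,
        qc_passed=qc.passed,
    )


def transfer_truth_labels(
    vessels: list[VesselObject], truth: GroundTruth
) -> list[str | None]:
    """Majority-overlap ground-truth class per recovered vessel.

    Returns one label per vessel (None when the vessel overlaps no
    planted object, e.g. a refinement artifact) and stores it on
    ``vessel.class_label`` is left untouched -- labels are returned so
    callers can decide whether they are training labels or truth.
    """
    labels: list[str | None] = []
    id_to_class = {v.vessel_id: v.class_label for v in truth.vessels}
    for v in vessels:
        ids = truth.label_image[v.rows, v.cols]
        ids = ids[ids > 0]
        if ids.size == 0:
            labels.append(None)
            continue
        vals, counts = np.unique(ids, return_counts=True)
        labels.append(id_to_class[int(vals[np.argmax(counts)])])
    return labels


def truth_marker_flags(
    vessels: list[VesselObject], truth: GroundTruth
) -> list[dict[str, bool] | None]:
    """Planted marker flags for each recovered vessel (majority overlap)."""
    id_to_flags = {v.vessel_id: v.marker_flags for v in truth.vessels}
    out = []
    for v in vessels:
        ids = truth.label_image[v.rows, v.cols]
        ids = ids[ids > 0]
        if ids.size == 0:
            out.append(None)
            continue
        vals, counts = np.unique(ids, return_counts=True)
        out.append(id_to_flags[int(vals[np.argmax(counts)])])
    return out


def simulate_and_process_cores(
    n_cores: int,
    config: ImageSimConfig | None = None,
    seed: int | None = None,
    cores_per_case: int = 2,
) -> tuple[list[CoreRecord], list[GroundTruth]]:
    """Simulate ``n_cores`` default cores and run the image stage.

    Cores are assigned to cases in blocks of ``cores_per_case`` (the
    study averaged ~1.7 cores per case; two is the typical design).
    Each core gets an independent child RNG stream from the one seed,
    so generation is reproducible regardless of processing order.
    """
    config = config or ImageSimConfig()
    root = np.random.default_rng(seed if seed is not None else config.seed)
    streams = root.spawn(n_cores)
    records: list[CoreRecord] = []
    truths: list[GroundTruth] = []
    for i, stream in enumerate(streams):
        stack, truth = generate_core_image(
            config, rng=stream, core_id=f"core-{i:04d}", batch_id=f"batch-{i // 8}"
        )
        case_id = f"case-{i // cores_per_case:04d}"
        rec = process_core(stack, case_id=case_id)
        labels = transfer_truth_labels(rec.vessels, truth)
        for v, lab in zip(rec.vessels, labels):
            v.class_label = lab
        records.append(rec)
        truths.append(truth)
    return records, truths


def recovered_marker_fractions(records: list[CoreRecord]) -> pd.Series:
    """Pooled marker-positive vessel fractions over all cores."""
    from vesselphen.preprocess import MARKERS

    total = sum(len(r.vessels) for r in records)
    if total == 0:
        raise ValueError("no vessels recovered")
    counts = {
        m: sum(
            1 for r in records for v in r.vessels if v.marker_flags.get(m, False)
        )
        for m in MARKERS
    }
    return pd.Series({m: c / total for m, c in counts.items()}, name="fraction")
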