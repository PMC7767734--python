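"""End-to-end convenience wrapper: image in, cell table out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cells import CellMasks, assign_stratum, grow_cell_masks
from .histocytometry import measure_cells
from .io import AnalysisConfig, MultiChannelImage
from .nuclei import NucleiSet, build_nuclei_map, detect_nuclei
from .strata import StrataMasks, brightfield_area, partition_strata, predict_epidermis


@dataclass
class PipelineResult:
    nuclei: NucleiSet
    nuclei_map: np.ndarray
    bf_area: np.ndarray
    epidermis: np.ndarray
    strata: StrataMasks
    cells: CellMasks
    table: pd.DataFrame


def run_pipeline(
    image: MultiChannelImage,
    config: Optional[AnalysisConfig] = None,
    manual_add: Optional[np.ndarray] = None,
    manual_remove: Optional[np.ndarray] = None,
) -> PipelineResult:
    """Nuclei -> strata -> cell masks -> per-cell measurements."""
    if config is None:
        config = AnalysisConfig(pixel_size_um=image.pixel_size_um)
    nuclei = detect_nuclei(image, config)
    nmap = build_nuclei_map(nuclei, config)
    bf = brightfield_area(image, config)
    epidermis = predict_epidermis(nmap, bf, manual_add, manual_remove)
    strata = partition_strata(epidermis, nuclei, config)
    cells = assign_stratum(grow_cell_masks(nuclei, strata, config), strata)
    table = measure_cells(cells, nuclei, image, bf_area=bf)
    return PipelineResult(nuclei=nuclei, nuclei_map=nmap, bf_area=bf,
                          epidermis=epidermis, strata=strata, cells=cells,
                          table=table)
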