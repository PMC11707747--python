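"""Threshold-based mIF quantification.

Cell-level measurements mirroring classic threshold-based image-analysis
tooling: cells are segmented from the DAPI stain (smoothed threshold,
distance-transform peak markers, watershed), tumor regions from the PanCK
stain, and a cell is positive for PD-L1 / CD3 / CD8 when the mean
intensity of the respective stain over its segmented pixels reaches the
marker threshold.  From the cell table the module derives, per region of
interest:

* PanCK-positive area (mm^2),
* positive cell density (cells/mm^2) and positive cell percentage (%),
* TPS — 100 x (PD-L1+ tumor cells) / (tumor cells),
* CPS — 100 x (PD-L1+ tumor + PD-L1+ immune cells) / (tumor cells),
  capped at 100 per clinical convention,
* colocalization counts for CD3&CD8 (cytotoxic T cells) and CD3&PD-L1
  (PD-L1+ T cells).

Three ROI definitions are supported: the whole tissue, the real tumor
region (used for both real and virtual measurements), and the respective
tumor region (each side uses its own PanCK segmentation).  Cells with no
tumor cells in the ROI yield an explicit undefined TPS/CPS (with reason),
never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, measure, morphology, segmentation

QUANT_MARKERS = ("PD-L1", "CD3", "CD8")
ROI_DEFINITIONS = ("tissue", "real_tumor", "respective_tumor")


@dataclass(frozen=True)
class QuantConfig:
    pixel_size_um: float = 0.25
    dapi_threshold: float | None = None  # None -> Otsu-like data-relative
    dapi_smooth_px: float = 1.0
    min_cell_area_px: int = 12
    marker_min_distance_px: int = 5  # nucleus-splitting peak separation
    marker_thresholds: dict = field(
        default_factory=lambda: {"PD-L1": 20.0, "CD3": 25.0, "CD8": 25.0}
    )
    panck_threshold: float | None = None  # None -> data-relative (half-Otsu)
    panck_smooth_px: float = 1.0
    panck_min_object_px: int = 64


@dataclass
class CellTable:
    """Per-cell measurements: centroid, area, marker means, flags."""

    df: pd.DataFrame  # id, x, y, area_um2, mean_<marker>, positive_<marker>, in_tumor
    label_image: np.ndarray
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        assert (self.df["area_um2"] > 0).all()
        for pair in (("CD3", "CD8"), ("CD3", "PD-L1")):
            both = (self.df[f"positive_{pair[0]}"] & self.df[f"positive_{pair[1]}"]).sum()
            assert both <= self.df[f"positive_{pair[0]}"].sum()
            assert both <= self.df[f"positive_{pair[1]}"].sum()


def segment_cells(dapi: np.ndarray, config: QuantConfig = QuantConfig()) -> CellTable:
    """Segment nuclei from the DAPI stain into a labeled cell table.

    Smoothed threshold -> distance transform -> peak markers -> watershed,
    so touching nuclei with distinct cores split into separate cells.
    An empty foreground returns an empty table, not an error.
    """
    dapi = np.asarray(dapi, float)
    if np.any(dapi < 0):
        raise ValueError("DAPI map must be nonnegative")
    sm = ndimage.gaussian_filter(dapi, config.dapi_smooth_px)
    if config.dapi_threshold is not None:
        thr = config.dapi_threshold
    else:
        # data-relative: Otsu when bimodal, else half the max
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(sm) if np.ptp(sm) > 0 else np.inf
    fg = sm > thr
    fg = morphology.remove_small_objects(fg, max_size=config.min_cell_area_px - 1)
    empty_cols = {
        "id": [], "x": [], "y": [], "area_um2": [],
        **{f"mean_{m}": [] for m in QUANT_MARKERS},
        **{f"positive_{m}": [] for m in QUANT_MARKERS},
        "in_tumor": [],
    }
    if not fg.any():
        return CellTable(
            df=pd.DataFrame(empty_cols),
            label_image=np.zeros(dapi.shape, dtype=np.int32),
            pixel_size_um=config.pixel_size_um,
        )

    dist = ndimage.distance_transform_edt(fg)
    peaks = feature.peak_local_max(
        dist,
        min_distance=config.marker_min_distance_px,
        labels=fg,
        exclude_border=False,
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(fg)
    labels = segmentation.watershed(-dist, markers, mask=fg)

    props = measure.regionprops(labels)
    area_scale = config.pixel_size_um**2
    rows = []
    for p in props:
        if p.area < config.min_cell_area_px:
            labels[labels == p.label] = 0
            continue
        cy, cx = p.centroid
        rows.append(
            {"id": p.label, "x": cx, "y": cy, "area_um2": p.area * area_scale}
        )
    df = pd.DataFrame(rows) if rows else pd.DataFrame(empty_cols)
    for m in QUANT_MARKERS:
        df[f"mean_{m}"] = 0.0
        df[f"positive_{m}"] = False
    df["in_tumor"] = False
    return CellTable(df=df, label_image=labels, pixel_size_um=config.pixel_size_um)


def segment_tumor(panck: np.ndarray, config: QuantConfig = QuantConfig()) -> np.ndarray:
    """Tumor mask from the PanCK stain: smoothed threshold, cleaned.

    The default threshold is data-relative (invariant to global intensity
    scaling); small objects and holes are removed.
    """
    panck = np.asarray(panck, float)
    sm = ndimage.gaussian_filter(panck, config.panck_smooth_px)
    if config.panck_threshold is not None:
        thr = config.panck_threshold
    else:
        if np.ptp(sm) == 0:
            return np.zeros(panck.shape, dtype=bool)
        from skimage.filters import threshold_otsu

        # half-Otsu: the Otsu split lands between the membranous region
        # level and bright cell bodies; halving it keeps the whole region
        thr = 0.5 * threshold_otsu(sm)
    mask = sm > thr
    mask = morphology.remove_small_objects(mask, max_size=config.panck_min_object_px - 1)
    mask = morphology.remove_small_holes(mask, max_size=config.panck_min_object_px - 1)
    return mask


def classify_positive(
    cells: CellTable, marker_map: np.ndarray, marker: str, threshold: float
) -> CellTable:
    """Set the positivity flag for one marker from its intensity map.

    A cell is positive iff the mean marker intensity over its segmented
    pixels is >= the threshold.
    """
    if marker not in QUANT_MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    marker_map = np.asarray(marker_map, float)
    if marker_map.shape != cells.label_image.shape:
        raise ValueError("marker map shape does not match the label image")
    if len(cells.df) == 0:
        return cells
    ids = cells.df["id"].to_numpy()
    means = ndimage.mean(marker_map, labels=cells.label_image, index=ids)
    cells.df[f"mean_{marker}"] = means
    cells.df[f"positive_{marker}"] = means >= threshold
    return cells


def assign_tumor_membership(cells: CellTable, tumor_mask: np.ndarray) -> CellTable:
    """in_tumor flag by centroid membership in the tumor mask."""
    if len(cells.df) == 0:
        return cells
    ys = cells.df["y"].round().astype(int).clip(0, tumor_mask.shape[0] - 1)
    xs = cells.df["x"].round().astype(int).clip(0, tumor_mask.shape[1] - 1)
    cells.df["in_tumor"] = tumor_mask[ys, xs]
    return cells


@dataclass
class MeasurementSet:
    """Measurements for one (image, ROI) combination.

    ``values`` maps measurement names to numbers; ``undefined`` maps
    names that could not be computed to the reason.
    """

    roi: str
    values: dict = field(default_factory=dict)
    undefined: dict = field(default_factory=dict)

    def get(self, name: str):
        return self.values.get(name)


def _density(count: int, area_mm2: float) -> float:
    return count / area_mm2 if area_mm2 > 0 else 0.0


def measure_roi(
    cells: CellTable,
    tumor_mask_real: np.ndarray,
    tumor_mask_virtual: np.ndarray | None,
    tissue_mask: np.ndarray,
    roi: str,
    panck_mask: np.ndarray | None = None,
) -> MeasurementSet:
    """Compute the measurement suite for one ROI definition.

    ``roi`` selects the region: ``tissue`` (whole tissue), ``real_tumor``
    (real PanCK mask on both sides) or ``respective_tumor`` (this image's
    own PanCK mask, which requires ``tumor_mask_virtual`` when measuring a
    virtual stain).  ``panck_mask`` is the PanCK segmentation of the image
    being measured, used for the positive-area measurement.
    """
    if roi not in ROI_DEFINITIONS:
        raise ValueError(f"unknown ROI {roi!r}")
    if roi == "tissue":
        region = tissue_mask
    elif roi == "real_tumor":
        region = tumor_mask_real
    else:
        if tumor_mask_virtual is None:
            raise ValueError("respective_tumor requires the virtual tumor mask")
        region = tumor_mask_virtual
    region = region & tissue_mask if roi != "tissue" else region

    px_mm2 = (cells.pixel_size_um / 1000.0) ** 2
    area_mm2 = float(region.sum()) * px_mm2
    ms = MeasurementSet(roi=roi)

    if panck_mask is not None:
        ms.values["panck_positive_area_mm2"] = float(
            (panck_mask & region).sum()
        ) * px_mm2

    df = cells.df
    if len(df):
        ys = df["y"].round().astype(int).clip(0, region.shape[0] - 1)
        xs = df["x"].round().astype(int).clip(0, region.shape[1] - 1)
        in_roi = region[ys, xs].to_numpy() if hasattr(region[ys, xs], "to_numpy") else region[ys, xs]
        sub = df[np.asarray(in_roi)]
    else:
        sub = df
    n_cells = len(sub)
    ms.values["dapi_cell_density"] = _density(n_cells, area_mm2)

    for m in QUANT_MARKERS:
        pos = int(sub[f"positive_{m}"].sum()) if n_cells else 0
        ms.values[f"{m}_cell_density"] = _density(pos, area_mm2)
        if m != "PD-L1":  # PD-L1 percentage is reported as TPS/CPS
            if n_cells:
                ms.values[f"{m}_positive_percentage"] = 100.0 * pos / n_cells
            else:
                ms.undefined[f"{m}_positive_percentage"] = "no segmented cells in ROI"

    # TPS / CPS from PD-L1 positivity and tumor membership
    if n_cells:
        tumor_cells = sub[sub["in_tumor"]]
        immune_cells = sub[~sub["in_tumor"]]
        n_tumor = len(tumor_cells)
        if n_tumor:
            pos_tumor = int(tumor_cells["positive_PD-L1"].sum())
            pos_immune = int(immune_cells["positive_PD-L1"].sum())
            ms.values["tps_percent"] = 100.0 * pos_tumor / n_tumor
            ms.values["cps_percent"] = min(
                100.0, 100.0 * (pos_tumor + pos_immune) / n_tumor
            )
        else:
            ms.undefined["tps_percent"] = "no tumor cells in ROI"
            ms.undefined["cps_percent"] = "no tumor cells in ROI"
    else:
        ms.undefined["tps_percent"] = "no segmented cells in ROI"
        ms.undefined["cps_percent"] = "no segmented cells in ROI"

    coloc = colocalization_counts(cells, region=region)
    for key, (count, density, pct) in coloc.items():
        ms.values[f"{key}_count"] = count
        ms.values[f"{key}_cell_density"] = _density(count, area_mm2)
        if pct is not None:
            ms.values[f"{key}_positive_percentage"] = pct
        else:
            ms.undefined[f"{key}_positive_percentage"] = "no segmented cells in ROI"
    return ms


COLOC_PAIRS = {
    "cd3_cd8": ("CD3", "CD8"),
    "cd3_pdl1": ("CD3", "PD-L1"),
}


def colocalization_counts(
    cells: CellTable,
    pairs: dict = COLOC_PAIRS,
    region: np.ndarray | None = None,
) -> dict:
    """Counts of cells positive for both markers of each pair.

    Returns {name: (count, density_placeholder, percentage or None)};
    CD3&CD8 colocalization identifies cytotoxic T cells, CD3&PD-L1 the
    PD-L1-positive T-cell subset.
    """
    for name, (m1, m2) in pairs.items():
        if m1 not in QUANT_MARKERS or m2 not in QUANT_MARKERS:
            raise ValueError(f"unknown marker pair {name}: ({m1}, {m2})")
    df = cells.df
    if region is not None and len(df):
        ys = df["y"].round().astype(int).clip(0, region.shape[0] - 1)
        xs = df["x"].round().astype(int).clip(0, region.shape[1] - 1)
        df = df[np.asarray(region[ys, xs])]
    out = {}
    n = len(df)
    for name, (m1, m2) in pairs.items():
        count = int((df[f"positive_{m1}"] & df[f"positive_{m2}"]).sum()) if n else 0
        pct = 100.0 * count / n if n else None
        out[name] = (count, None, pct)
    return out


def quantify_mif(
    mif_channels: dict,
    config: QuantConfig = QuantConfig(),
    tissue: np.ndarray | None = None,
    tumor_mask_real: np.ndarray | None = None,
    rois: tuple = ROI_DEFINITIONS,
) -> tuple[CellTable, dict]:
    """Full measurement suite for one mIF image.

    ``mif_channels`` maps channel names (``DAPI``, ``PanCK``, ``PD-L1``,
    ``CD3``, ``CD8``) to 2-D intensity maps.  Returns the cell table and
    a dict {roi: MeasurementSet}.  ``tumor_mask_real`` defaults to this
    image's own PanCK mask (the real-stain case).
    """
    from .sampling import tissue_mask as _tissue_detect

    dapi = mif_channels["DAPI"]
    panck = mif_channels["PanCK"]
    cells = segment_cells(dapi, config)
    tumor_own = segment_tumor(panck, config)
    if tissue is None:
        tissue = _tissue_detect(np.stack([dapi, panck], axis=-1))
    if tumor_mask_real is None:
        tumor_mask_real = tumor_own
    for m in QUANT_MARKERS:
        cells = classify_positive(cells, mif_channels[m], m, config.marker_thresholds[m])
    cells = assign_tumor_membership(cells, tumor_own)
    cells.validate()
    results = {}
    for roi in rois:
        results[roi] = measure_roi(
            cells,
            tumor_mask_real=tumor_mask_real,
            tumor_mask_virtual=tumor_own,
            tissue_mask=tissue,
            roi=roi,
            panck_mask=tumor_own,
        )
    return cells, results
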