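"""Batch extraction: biometry + scans in, tidy sector table out.

Runs the per-eye chain — quality filter, thickness map, fovea location,
raw and corrected ETDRS grids, sector averaging — over a whole cohort,
logging per-eye exclusions instead of aborting.
"""

from __future__ import annotations

import logging

import pandas as pd

from .etdrs import SECTORS, extract_eye
from .geometry import ScanGeometry, quality_filter
from .synthetic import _eye_biometry_from_row
from .thickness import SegmentedSurfaces, ThicknessMap

__all__ = ["extract_cohort", "sector_records"]

log = logging.getLogger(__name__)


def sector_records(raw, corrected) -> list[dict]:
    """Two tidy rows per sector from one eye's paired sector means."""
    rows = []
    for st in (raw, corrected):
        bio = st.biometry
        for sector in SECTORS:
            rows.append({
                "participant_id": bio.participant_id,
                "eye": bio.eye,
                "corrected": st.corrected,
                "sector": sector,
                "mean_um": st.means[sector],
                "n_pixels": st.counts[sector],
                "truncation_fraction": st.truncation.get(sector, 0.0),
            })
    return rows


def extract_cohort(biometry_df: pd.DataFrame,
                   scans: dict[tuple[str, str],
                               ThicknessMap | SegmentedSurfaces],
                   geometry: ScanGeometry,
                   nasal_side: str | None = None,
                   search_radius_mm: float = 1.5,
                   smooth_mm: float = 0.25,
                   ) -> tuple[pd.DataFrame, list[dict]]:
    """Sector means for every adequate-quality eye in a cohort.

    Returns the tidy sector table (one row per eye × correction state ×
    sector) and an exclusion log.  Eyes failing the SNR filter, missing a
    scan, or failing extraction are logged and skipped; an empty survivor
    set raises.
    """
    eyes = [_eye_biometry_from_row(row) for _, row in biometry_df.iterrows()]
    retained, excluded = quality_filter(eyes)
    rows: list[dict] = []
    for bio in retained:
        key = (bio.participant_id, bio.eye)
        scan = scans.get(key)
        if scan is None:
            excluded.append({"participant_id": bio.participant_id,
                             "eye": bio.eye, "reason": "missing_scan"})
            continue
        try:
            raw, corr = extract_eye(scan, bio, geometry,
                                    nasal_side=nasal_side,
                                    search_radius_mm=search_radius_mm,
                                    smooth_mm=smooth_mm)
        except (ValueError, RuntimeError) as exc:
            excluded.append({"participant_id": bio.participant_id,
                             "eye": bio.eye,
                             "reason": f"extraction_failed: {exc}"})
            continue
        rows.extend(sector_records(raw, corr))
    if not rows:
        raise RuntimeError("no eyes survived extraction")
    if excluded:
        log.info("extract_cohort: %d eyes excluded", len(excluded))
    return pd.DataFrame(rows), excluded
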