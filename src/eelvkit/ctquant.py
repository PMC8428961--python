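"""Quantitative CT lung analysis.

Per-voxel gas and tissue volumes from the CT number, aeration compartments,
end-expiratory lung volume (EELV_CT) as the summed voxel gas volume, and
CT-derived recruitment between two PEEP levels.

The voxel rule is the standard linear density mixture on the Hounsfield
scale (-1000 HU = gas, 0 HU = water/tissue):

    gas = -HU/1000 * voxel volume   for -1000 <= HU <= 0
    gas = 0                         for HU > 0
    gas = voxel volume              for HU < -1000
    tissue = voxel volume - gas

Compartments by HU: non-inflated [+100, -100], poorly inflated
[-101, -500], normally inflated [-501, -900], overinflated [-901, -1000].
HU values are real-valued, so the printed integer bin edges are widened by
0.5 to half-open intervals; masked voxels above +100 HU are counted as
non-inflated (pure tissue) rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DataError, EmptyMaskError, InvalidConfigError

__all__ = [
    "CTImage",
    "AerationReport",
    "COMPARTMENT_NAMES",
    "voxel_gas_volume",
    "aeration_report",
    "vrec_ct",
    "read_nifti_pair",
    "write_nifti",
]

COMPARTMENT_NAMES = (
    "non_inflated",
    "poorly_inflated",
    "normally_inflated",
    "overinflated",
)
# real-valued bin edges between compartments (printed integer edges +/- 0.5)
_EDGES = (-900.5, -500.5, -100.5)


@dataclass
class CTImage:
    """An HU grid with a binary lung mask on the same voxel grid."""

    hu: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    mask: np.ndarray
    phase: Literal["end-expiration", "end-inspiration"] = "end-expiration"

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.hu.shape != self.mask.shape:
            raise InvalidConfigError("hu and mask shapes differ")
        if any(d <= 0 for d in self.voxel_dims_mm):
            raise InvalidConfigError("voxel dims must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_dims_mm)) / 1000.0


@dataclass
class AerationReport:
    """Gas/tissue and aeration-compartment volumes of one masked CT (mL)."""

    gas_ml: float
    tissue_ml: float
    compartments: dict[str, float]
    gas_fraction_aerated: float
    tissue_nonaerated_ml: float
    phase: str = "end-expiration"

    @property
    def eelv_ct_ml(self) -> float:
        """Total voxel gas volume; EELV when measured at end-expiration."""
        return self.gas_ml

    @property
    def lung_volume_ml(self) -> float:
        return self.gas_ml + self.tissue_ml

    def to_dict(self) -> dict:
        return {
            "gas_ml": self.gas_ml,
            "tissue_ml": self.tissue_ml,
            "lung_volume_ml": self.lung_volume_ml,
            "compartments_ml": dict(self.compartments),
            "gas_fraction_aerated": self.gas_fraction_aerated,
            "tissue_nonaerated_ml": self.tissue_nonaerated_ml,
            "phase": self.phase,
        }


def voxel_gas_volume(hu, voxel_volume):
    """Gas volume of a voxel (same units as ``voxel_volume``); vectorized.

    Piecewise: ``-HU/1000 * v`` on [-1000, 0], ``0`` above 0 HU, the full
    voxel below -1000 HU.
    """
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise DataError("non-finite HU values")
    frac = np.clip(-hu / 1000.0, 0.0, 1.0)
    result = frac * voxel_volume
    return result if result.ndim else float(result)


def aeration_report(img: CTImage) -> AerationReport:
    """Gas/tissue volumes and the four aeration compartments over the mask."""
    if not img.mask.any():
        raise EmptyMaskError("lung mask selects no voxels")
    v = img.voxel_volume_ml
    hu = img.hu[img.mask]
    gas = voxel_gas_volume(hu, v)
    tissue = v - gas

    # bins are half-open with the upper edge included, so an integer HU of
    # e.g. -500 is poorly and -501 normally inflated, as printed
    comp_idx = np.digitize(hu, _EDGES, right=True)  # 0 overinf ... 3 non-inflated
    compartments = {
        name: float(np.count_nonzero(comp_idx == 3 - i) * v)
        for i, name in enumerate(COMPARTMENT_NAMES)
    }

    aerated = comp_idx < 3  # everything but non-inflated
    aerated_vol = float(np.count_nonzero(aerated) * v)
    gas_aerated = float(np.sum(gas[aerated]))
    gas_fraction_aerated = gas_aerated / aerated_vol if aerated_vol > 0 else 0.0
    tissue_nonaerated = float(np.sum(tissue[comp_idx == 3]))

    return AerationReport(
        gas_ml=float(np.sum(gas)),
        tissue_ml=float(np.sum(tissue)),
        compartments=compartments,
        gas_fraction_aerated=gas_fraction_aerated,
        tissue_nonaerated_ml=tissue_nonaerated,
        phase=img.phase,
    )


def vrec_ct(report_low: AerationReport, report_high: AerationReport) -> float:
    """CT-derived recruited volume (mL) between two end-expiratory scans.

    ``report_low`` is the lower-PEEP measurement (rank n), ``report_high``
    the next (rank n+1). Recruitment converts non-aerated tissue into
    aerated lung, so the recruited *gas* volume is the non-aerated tissue
    lost, scaled by the aerated-region gas/tissue ratio at the lower PEEP:

        Vrec = (Vtis_n - Vtis_n+1) / (1 - Fgas_n) * Fgas_n

    Negative values indicate derecruitment.
    """
    fgas = report_low.gas_fraction_aerated
    if fgas >= 1.0:
        raise ZeroDivisionError(
            "aerated gas fraction is 1; the recruitment formula is degenerate"
        )
    dtis = report_low.tissue_nonaerated_ml - report_high.tissue_nonaerated_ml
    return dtis / (1.0 - fgas) * fgas


# ---------------------------------------------------------------------------
# NIfTI I/O (mask and HU must share the grid; no resampling is attempted)


def read_nifti_pair(ct_path, mask_path, phase="end-expiration") -> CTImage:
    """Load an HU volume and its binary lung mask from NIfTI-1 files."""
    import nibabel as nib

    ct = nib.load(str(ct_path))
    mk = nib.load(str(mask_path))
    hu = np.asarray(ct.get_fdata(), dtype=float)
    mask = np.asarray(mk.get_fdata()) > 0.5
    if hu.shape != mask.shape:
        raise DataError(f"CT grid {hu.shape} != mask grid {mask.shape}")
    zooms = ct.header.get_zooms()[:3]
    return CTImage(hu=hu, voxel_dims_mm=tuple(float(z) for z in zooms),
                   mask=mask, phase=phase)


def write_nifti(img: CTImage, ct_path, mask_path) -> None:
    """Write the HU volume (float32) and mask (uint8) as NIfTI-1 files."""
    import nibabel as nib

    affine = np.diag(list(img.voxel_dims_mm) + [1.0])
    nib.save(nib.Nifti1Image(img.hu.astype(np.float32), affine), str(ct_path))
    nib.save(nib.Nifti1Image(img.mask.astype(np.uint8), affine), str(mask_path))
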