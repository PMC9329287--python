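"""Combined cortical/subcortical parcellation: region table, homologue pairing,
and the coordinate systems every downstream stage consumes.

The default table follows the Desikan-Killiany cortical atlas (34 regions per
hemisphere) plus 14 subcortical structures (bilateral accumbens, amygdala,
caudate, hippocampus, pallidum, putamen, thalamus).  Region ordering is fixed:
cortical homologue pairs first (left before right within each pair, pairs in
alphabetical order of the base name), then subcortical pairs in the same
scheme.  Matrices everywhere in the package are indexed identically to these
rows, 0-based.

The packaged coordinates are synthetic-but-plausible: the real study surface
(a merged, inflated cortical + subcortical mesh mapped to a sphere) is not
redistributable, so cortical regions are laid out on two hemispheric caps of a
unit sphere and subcortical regions sit near the inter-hemispheric rim.  Spin
permutation only needs coordinates with realistic spatial adjacency; users
with real surface coordinates can supply their own CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionTable",
    "ValidationError",
    "DK_CORTICAL",
    "SUBCORTICAL",
    "default_region_table",
    "load_region_table",
    "save_region_table",
    "hemisphere_swap_order",
]


class ValidationError(ValueError):
    """Raised when an input table or cohort violates its contract."""


# Desikan-Killiany cortical parcels (base names, one per homologue pair).
DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]

# Subcortical grey-matter structures (base names); bilateral, so 14 regions.
SUBCORTICAL = [
    "accumbens", "amygdala", "caudate", "hippocampus",
    "pallidum", "putamen", "thalamus",
]

_COLUMNS = ["name", "hemisphere", "class", "homologue",
            "x", "y", "z", "sx", "sy", "sz"]


@dataclass
class RegionTable:
    """Validated region table; rows define the global region indexing.

    Attributes
    ----------
    frame
        DataFrame with columns name, hemisphere ({left, right}), class
        ({cortical, subcortical}), homologue (region_id of the contralateral
        homologue), x/y/z (anatomical mm) and sx/sy/sz (unit-sphere
        coordinates on the merged inflated surface).
    """

    frame: pd.DataFrame
    _sphere: np.ndarray = field(init=False, repr=False)
    _xyz: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"region table missing columns: {missing}")
        if df["name"].duplicated().any():
            dupes = df.loc[df["name"].duplicated(), "name"].tolist()
            raise ValidationError(f"duplicate region names: {dupes}")
        bad_hemi = set(df["hemisphere"]) - {"left", "right"}
        if bad_hemi:
            raise ValidationError(f"invalid hemisphere labels: {bad_hemi}")
        bad_cls = set(df["class"]) - {"cortical", "subcortical"}
        if bad_cls:
            raise ValidationError(f"invalid structure classes: {bad_cls}")

        n = len(df)
        hom = df["homologue"].to_numpy(dtype=int)
        if np.any((hom < 0) | (hom >= n)):
            raise ValidationError("homologue index out of range")
        if np.any(hom == np.arange(n)):
            fixed = df.index[hom == np.arange(n)].tolist()
            raise ValidationError(
                f"homologue pairing maps region(s) {fixed} to themselves; "
                "pairing must be a fixed-point-free involution")
        if not np.array_equal(hom[hom], np.arange(n)):
            raise ValidationError("homologue pairing is not symmetric")

        sphere = df[["sx", "sy", "sz"]].to_numpy(dtype=float)
        norms = np.linalg.norm(sphere, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            worst = int(np.argmax(np.abs(norms - 1.0)))
            raise ValidationError(
                f"sphere coordinate of region {worst} has norm {norms[worst]!r}; "
                "expected unit norm within 1e-9")
        self._sphere = sphere
        self._xyz = df[["x", "y", "z"]].to_numpy(dtype=float)

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_regions(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return self.frame["name"].tolist()

    @property
    def homologue(self) -> np.ndarray:
        return self.frame["homologue"].to_numpy(dtype=int)

    @property
    def sphere_xyz(self) -> np.ndarray:
        """(n, 3) unit-sphere coordinates."""
        return self._sphere

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) anatomical coordinates in mm."""
        return self._xyz

    @property
    def cortical_mask(self) -> np.ndarray:
        return (self.frame["class"] == "cortical").to_numpy()

    @property
    def subcortical_mask(self) -> np.ndarray:
        return (self.frame["class"] == "subcortical").to_numpy()


def _cap_points(n: int, center_sign: float, theta_max: float) -> np.ndarray:
    """Deterministic Fibonacci-spiral layout of n points on a spherical cap.

    The cap is centred on (center_sign, 0, 0); theta_max is the polar half-angle
    of the cap in radians.
    """
    i = np.arange(n) + 0.5
    # uniform in cap area: cos(theta) uniform on [cos(theta_max), 1]
    cos_t = 1.0 - (1.0 - np.cos(theta_max)) * i / n
    theta = np.arccos(cos_t)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n)
    # local frame: cap axis along +x, then mirrored for the left hemisphere
    x = np.cos(theta) * center_sign
    y = np.sin(theta) * np.cos(phi)
    z = np.sin(theta) * np.sin(phi)
    return np.column_stack([x, y, z])


def default_region_table() -> RegionTable:
    """Build the packaged 82-region table with synthetic sphere coordinates.

    68 cortical rows (left/right interleaved per homologue pair) followed by 14
    subcortical rows in the same scheme.  Coordinates are mirror-symmetric
    across hemispheres: cortical parcels occupy two hemispheric caps, the
    subcortical structures a narrow band near the inter-hemispheric rim.
    Anatomical xyz places cortex on a 70 mm shell and subcortex on a 30 mm
    shell around the origin.
    """
    n_cort = len(DK_CORTICAL)
    cort_right = _cap_points(n_cort, +1.0, np.deg2rad(70.0))
    # subcortical points sit near the inter-hemispheric rim (theta 75-85 deg)
    sub_theta = np.deg2rad(np.linspace(75.0, 85.0, len(SUBCORTICAL)))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    sub_phi = golden * np.arange(len(SUBCORTICAL)) + 1.0
    sub_right = np.column_stack([
        np.cos(sub_theta),
        np.sin(sub_theta) * np.cos(sub_phi),
        np.sin(sub_theta) * np.sin(sub_phi),
    ])

    rows = []

    def add_pair(base: str, cls: str, unit: np.ndarray, radius: float, idx: int) -> None:
        mirrored = unit * np.array([-1.0, 1.0, 1.0])
        rows.append({
            "name": f"left_{base}", "hemisphere": "left", "class": cls,
            "homologue": idx + 1,
            "x": radius * mirrored[0], "y": radius * mirrored[1],
            "z": radius * mirrored[2],
            "sx": mirrored[0], "sy": mirrored[1], "sz": mirrored[2],
        })
        rows.append({
            "name": f"right_{base}", "hemisphere": "right", "class": cls,
            "homologue": idx,
            "x": radius * unit[0], "y": radius * unit[1], "z": radius * unit[2],
            "sx": unit[0], "sy": unit[1], "sz": unit[2],
        })

    for k, base in enumerate(DK_CORTICAL):
        add_pair(base, "cortical", cort_right[k], 70.0, 2 * k)
    off = 2 * n_cort
    for k, base in enumerate(SUBCORTICAL):
        add_pair(base, "subcortical", sub_right[k], 30.0, off + 2 * k)

    frame = pd.DataFrame(rows, columns=_COLUMNS)
    sphere = frame[["sx", "sy", "sz"]].to_numpy()
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    frame[["sx", "sy", "sz"]] = sphere
    return RegionTable(frame)


def load_region_table(path) -> RegionTable:
    """Load and validate a region table CSV.

    The CSV must carry columns name, hemisphere, class, homologue, x, y, z,
    sx, sy, sz; rows define the region indexing (order preserved).
    """
    df = pd.read_csv(path)
    return RegionTable(df.reset_index(drop=True))


def save_region_table(table: RegionTable, path) -> None:
    table.frame.to_csv(path, index=False)


def hemisphere_swap_order(table: RegionTable) -> np.ndarray:
    """Permutation exchanging every region with its contralateral homologue.

    Applying the permutation twice is the identity; used to re-sort
    right-focus patients into ipsilateral/contralateral convention.
    """
    return table.homologue.copy()
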