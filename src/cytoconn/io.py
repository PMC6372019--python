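"""File formats: PNG sections with JSON sidecars, NIfTI orientation fields,
TSV matrices / geometry / profile tables, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .connectome import ConnectivityMatrix
from .profiles import PointPair, Profile, RegionalProfile
from .similarity import SimilarityMatrix
from .synthetic_data import AnnulusGeometry, OrientationField, RegionGeometry, StainedSection

__all__ = [
    "write_section",
    "read_section",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_geometry_tsv",
    "read_geometry_tsv",
    "write_profiles_tsv",
    "write_regional_profiles_tsv",
    "write_orientation_field",
    "read_orientation_field",
    "read_point_pairs_json",
    "write_point_pairs_json",
]


def _rle_encode(flat: np.ndarray) -> tuple[list[int], list[int]]:
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(flat)]])
    return flat[starts].tolist(), (ends - starts).tolist()


def _rle_decode(values, lengths) -> np.ndarray:
    return np.repeat(np.asarray(values, dtype=int), np.asarray(lengths, dtype=int))


def write_section(section: StainedSection, png_path, sidecar_path=None) -> None:
    """16-bit grayscale PNG (intensities clipped to [0, 1]) plus a JSON
    sidecar holding surface curves, run-length-encoded labels, the ribbon
    geometry and the truth curves."""
    png_path = Path(png_path)
    sidecar_path = Path(sidecar_path or png_path.with_suffix(".json"))
    img16 = np.round(np.clip(section.image, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(img16).save(png_path)
    values, lengths = _rle_encode(section.label_map.ravel())
    geo = section.geometry
    sidecar = {
        "section_id": section.section_id,
        "shape": list(section.image.shape),
        "pial_curve": section.pial_curve.tolist(),
        "wm_curve": section.wm_curve.tolist(),
        "labels_rle": {"values": values, "lengths": lengths},
        "geometry": {
            "center": list(geo.center),
            "r_pial": geo.r_pial,
            "r_wm": geo.r_wm,
            "n_regions": geo.n_regions,
            "theta0": geo.theta0,
        },
        "truth_profiles": {str(r): c.tolist() for r, c in section.truth_profiles.items()},
    }
    sidecar_path.write_text(json.dumps(sidecar))


def read_section(png_path, sidecar_path=None) -> StainedSection:
    png_path = Path(png_path)
    sidecar_path = Path(sidecar_path or png_path.with_suffix(".json"))
    image = np.asarray(Image.open(png_path), dtype=float) / 65535.0
    meta = json.loads(sidecar_path.read_text())
    label_map = _rle_decode(**meta["labels_rle"]).reshape(meta["shape"])
    g = meta["geometry"]
    return StainedSection(
        image=image,
        label_map=label_map,
        pial_curve=np.array(meta["pial_curve"]),
        wm_curve=np.array(meta["wm_curve"]),
        truth_profiles={int(r): np.array(c) for r, c in meta["truth_profiles"].items()},
        geometry=AnnulusGeometry(
            center=tuple(g["center"]),
            r_pial=g["r_pial"],
            r_wm=g["r_wm"],
            n_regions=g["n_regions"],
            theta0=g["theta0"],
        ),
        section_id=meta["section_id"],
    )


def write_matrix_tsv(matrix: np.ndarray, region_ids, path) -> None:
    ids = [int(r) for r in region_ids]
    pd.DataFrame(np.asarray(matrix), index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), df.index.to_numpy()


def write_geometry_tsv(geometry: list[RegionGeometry], path) -> None:
    rows = [
        {
            "region": g.region,
            "x": g.centroid[0],
            "y": g.centroid[1],
            "z": g.centroid[2],
            "volume": g.volume,
            "area": g.surface_area,
            "hemisphere": g.hemisphere,
        }
        for g in sorted(geometry, key=lambda g: g.region)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_geometry_tsv(path) -> list[RegionGeometry]:
    df = pd.read_csv(path, sep="\t")
    return [
        RegionGeometry(
            region=int(r.region),
            centroid=np.array([r.x, r.y, r.z]),
            volume=float(r.volume),
            surface_area=float(r.area),
            hemisphere=str(r.hemisphere),
        )
        for r in df.itertuples()
    ]


def write_profiles_tsv(profiles: list[Profile], path) -> None:
    rows = []
    for p in profiles:
        row = {"pair_id": p.pair_id, "region": p.region}
        row.update({f"v{k}": v for k, v in enumerate(p.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_regional_profiles_tsv(regional: list[RegionalProfile], path) -> None:
    rows = []
    for r in regional:
        row = {
            "region": r.region,
            "n_profiles": r.n_profiles,
            "included": int(r.included),
            "mean_thickness": r.mean_thickness,
        }
        row.update({f"v{k}": v for k, v in enumerate(r.mean_profile)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_orientation_field(field: OrientationField, prefix) -> None:
    """NIfTI volumes: <prefix>_dirs.nii (4-D), _fa.nii, _labels.nii."""
    prefix = Path(prefix)
    aff = np.eye(4)
    nib.save(nib.Nifti1Image(field.dirs.astype(np.float32), aff), f"{prefix}_dirs.nii")
    nib.save(nib.Nifti1Image(field.fa.astype(np.float32), aff), f"{prefix}_fa.nii")
    nib.save(
        nib.Nifti1Image(field.labels.astype(np.int16), aff), f"{prefix}_labels.nii"
    )


def read_orientation_field(prefix) -> OrientationField:
    prefix = Path(prefix)
    dirs = np.asarray(nib.load(f"{prefix}_dirs.nii").dataobj, dtype=float)
    fa = np.asarray(nib.load(f"{prefix}_fa.nii").dataobj, dtype=float)
    labels = np.asarray(nib.load(f"{prefix}_labels.nii").dataobj, dtype=int)
    return OrientationField(
        dirs=dirs, fa=fa, labels=labels, mask=np.ones(fa.shape, dtype=bool)
    )


def write_point_pairs_json(pairs: list[PointPair], path, section_id: str = "0") -> None:
    payload = {
        "section_id": section_id,
        "pairs": [
            {"pair_id": p.pair_id, "pial": p.pial.tolist(), "wm": p.wm.tolist()}
            for p in pairs
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_point_pairs_json(path) -> list[PointPair]:
    meta = json.loads(Path(path).read_text())
    return [
        PointPair(
            pair_id=int(p["pair_id"]),
            pial=np.array(p["pial"]),
            wm=np.array(p["wm"]),
            section_id=str(meta.get("section_id", "0")),
        )
        for p in meta["pairs"]
    ]
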