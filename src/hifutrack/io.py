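"""NIfTI / JSON readers and writers, session manifests.

Conventions:

* images: NIfTI-1, the stored 4x4 affine is the voxel-to-world map in mm.
  2D images are stored with a trailing singleton dimension and squeezed on
  load (the third affine column, the slice normal scaled by the slice
  thickness, survives the round trip).
* deformation fields: NIfTI with a trailing vector dimension (components
  in mm along the grid axes).
* masks: uint8 NIfTI.
* temperature series: 4D NIfTI (2D + t) plus a JSON sidecar with the
  frame interval and plane label.
* manifests, plans, reports: JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import DeformationField, GeomImage, ROIMask
from .session import (
    SonicationBundle,
    SonicationCell,
    SonicationPlan,
    TherapySession,
)
from .thermal_dose import TemperatureSeries

ROLES = (
    "reference_anchor",
    "anchor",
    "ref2d",
    "nondistorted_epi",
    "sparse_anchor",
    "thermo_magnitude",
    "thermo_series",
)


class ManifestError(ValueError):
    """Structured manifest validation failure."""


# ---------------------------------------------------------------------------
# images, fields, masks
# ---------------------------------------------------------------------------


def save_image(img: GeomImage, path) -> None:
    data = img.data if img.ndim == 3 else img.data[..., None]
    nib.save(nib.Nifti1Image(data.astype(np.float64), img.affine), str(path))


def load_image(path) -> GeomImage:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    return GeomImage(data, np.asarray(nii.affine))


def save_field(fld: DeformationField, path) -> None:
    vec = fld.vectors
    if fld.ndim == 2:
        vec = vec[:, :, None, :]  # (n0, n1, 1, ncomp)
    nib.save(nib.Nifti1Image(vec.astype(np.float64), fld.geometry.affine), str(path))


def load_field(path) -> DeformationField:
    nii = nib.load(str(path))
    vec = np.asarray(nii.dataobj, dtype=float)
    affine = np.asarray(nii.affine)
    if vec.ndim == 4 and vec.shape[2] == 1 and vec.shape[3] == 2:
        vec = vec[:, :, 0, :]
        geom = GeomImage(np.zeros(vec.shape[:2]), affine)
    elif vec.ndim == 4 and vec.shape[3] == 3:
        geom = GeomImage(np.zeros(vec.shape[:3]), affine)
    else:
        raise ValueError(f"unrecognised field layout {vec.shape}")
    return DeformationField(vec, geom)


def save_mask(mask: ROIMask, geom: GeomImage, path) -> None:
    data = mask.mask.astype(np.uint8)
    if data.ndim == 2:
        data = data[..., None]
    nib.save(nib.Nifti1Image(data, geom.affine), str(path))


def load_mask(path) -> tuple[ROIMask, GeomImage]:
    img = load_image(path)
    return ROIMask(img.data > 0.5), img


def save_series(series: TemperatureSeries, path) -> None:
    stack = np.stack([f.data for f in series.frames], axis=-1)[:, :, None, :]
    nib.save(
        nib.Nifti1Image(stack.astype(np.float64), series.geometry.affine), str(path)
    )
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    sidecar.write_text(
        json.dumps({"dt_s": series.dt_s, "plane": series.plane})
    )


def load_series(path) -> TemperatureSeries:
    nii = nib.load(str(path))
    stack = np.asarray(nii.dataobj, dtype=float)[:, :, 0, :]
    affine = np.asarray(nii.affine)
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    frames = [GeomImage(stack[..., i], affine) for i in range(stack.shape[-1])]
    return TemperatureSeries(frames, float(meta["dt_s"]), meta.get("plane", ""))


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------


def save_plan(plan: SonicationPlan, path) -> None:
    payload = {
        "cells": [
            {
                "centre_mm": list(c.centre_mm),
                "semi_axes_mm": list(c.semi_axes_mm),
                "energy_j": c.energy_j,
                "out_of_extent": c.out_of_extent,
            }
            for c in plan.cells
        ]
    }
    Path(str(path)).write_text(json.dumps(payload, indent=1))


def load_plan(path) -> SonicationPlan:
    payload = json.loads(Path(str(path)).read_text())
    return SonicationPlan(
        [
            SonicationCell(
                centre_mm=np.asarray(c["centre_mm"], float),
                semi_axes_mm=np.asarray(c["semi_axes_mm"], float),
                energy_j=float(c.get("energy_j", 0.0)),
                out_of_extent=bool(c.get("out_of_extent", False)),
            )
            for c in payload["cells"]
        ]
    )


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


@dataclass
class ScanEntry:
    path: str
    role: str
    timestamp_s: float
    gating_window_mm: float | None = None
    plane: str | None = None
    bundle: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ManifestError(f"{self.path}: unknown role {self.role!r}")


@dataclass
class SessionManifest:
    scans: list
    plan_path: str
    output_dir: str = "."

    def __post_init__(self) -> None:
        refs = [s for s in self.scans if s.role == "reference_anchor"]
        if len(refs) != 1:
            raise ManifestError(
                f"manifest must contain exactly one reference_anchor, got {len(refs)}"
            )
        by_role: dict = {}
        for s in self.scans:
            by_role.setdefault((s.role, s.plane, s.bundle), []).append(s.timestamp_s)
        for key, ts in by_role.items():
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ManifestError(
                    f"timestamps not strictly increasing for role chain {key}"
                )
        anchor_t = min(s.timestamp_s for s in self.scans if s.role == "reference_anchor")
        for s in self.scans:
            if s.role != "reference_anchor" and s.timestamp_s < anchor_t:
                raise ManifestError(
                    f"{s.path}: acquired before the reference anchor"
                )


def write_manifest(manifest: SessionManifest, path) -> None:
    payload = {
        "scans": [asdict(s) for s in manifest.scans],
        "plan_path": manifest.plan_path,
        "output_dir": manifest.output_dir,
    }
    Path(str(path)).write_text(json.dumps(payload, indent=1))


def read_manifest(path) -> SessionManifest:
    try:
        payload = json.loads(Path(str(path)).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    try:
        scans = [ScanEntry(**s) for s in payload["scans"]]
    except (KeyError, TypeError) as exc:
        raise ManifestError(f"{path}: malformed scan entry ({exc})") from exc
    return SessionManifest(
        scans=scans,
        plan_path=payload["plan_path"],
        output_dir=payload.get("output_dir", "."),
    )


def load_scan(entry: ScanEntry, base_dir=".") -> GeomImage:
    p = Path(base_dir) / entry.path
    if not p.exists():
        raise ManifestError(f"scan file missing: {p} (role {entry.role})")
    return load_image(p)


# ---------------------------------------------------------------------------
# whole-session round trip
# ---------------------------------------------------------------------------


def write_session(session: TherapySession, out_dir) -> Path:
    """Serialise a session (NIfTI scans + JSON manifest/plan); returns manifest path."""
    out = Path(str(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    scans: list[ScanEntry] = []

    def add(img, role, t, plane=None, bundle=None, window=None):
        tag = role if bundle is None else f"b{bundle:02d}_{role}"
        if plane:
            tag += f"_{plane}"
        fname = f"{tag}_{len(scans):03d}.nii"
        save_image(img, out / fname)
        scans.append(
            ScanEntry(
                path=fname,
                role=role,
                timestamp_s=float(t),
                plane=plane,
                bundle=bundle,
                gating_window_mm=window,
            )
        )

    narrow = session.gating.get("reference_mm")
    wide = session.gating.get("thermometry_mm")
    for k, (t, img) in enumerate(zip(session.anchor_times_s, session.anchors)):
        add(img, "reference_anchor" if k == 0 else "anchor", t, window=narrow)
    for j, b in enumerate(session.bundles):
        for plane in b.planes:
            add(b.ref2d[plane], "ref2d", b.timestamp_s, plane, j, narrow)
            if b.nondistorted_epi is not None:
                add(
                    b.nondistorted_epi[plane], "nondistorted_epi",
                    b.timestamp_s + 0.01, plane, j, narrow,
                )
            if b.sparse_anchor is not None:
                add(
                    b.sparse_anchor[plane], "sparse_anchor",
                    b.timestamp_s + 0.02, plane, j, narrow,
                )
            for i, mag in enumerate(b.thermo_magnitude[plane]):
                add(
                    mag, "thermo_magnitude",
                    b.timestamp_s + 1.0 + i, plane, j, wide,
                )
            series = b.thermo_temperature[plane]
            sname = f"b{j:02d}_thermo_series_{plane}.nii"
            save_series(series, out / sname)
            scans.append(
                ScanEntry(
                    path=sname,
                    role="thermo_series",
                    timestamp_s=float(b.timestamp_s + 1.0),
                    plane=plane,
                    bundle=j,
                    gating_window_mm=wide,
                )
            )
    save_plan(session.plan, out / "plan.json")
    manifest = SessionManifest(scans=scans, plan_path="plan.json", output_dir=".")
    write_manifest(manifest, out / "session.json")
    return out / "session.json"


def load_session(manifest_path) -> TherapySession:
    manifest = read_manifest(manifest_path)
    base = Path(str(manifest_path)).parent
    anchors, anchor_times = [], []
    reference = None
    bundles_raw: dict = {}
    for entry in sorted(manifest.scans, key=lambda s: s.timestamp_s):
        if entry.role in ("reference_anchor", "anchor"):
            img = load_scan(entry, base)
            if entry.role == "reference_anchor":
                reference = img
                anchors.insert(0, img)
                anchor_times.insert(0, entry.timestamp_s)
            else:
                anchors.append(img)
                anchor_times.append(entry.timestamp_s)
        else:
            bundles_raw.setdefault(entry.bundle, []).append(entry)
    bundles = []
    for j in sorted(k for k in bundles_raw.keys() if k is not None):
        entries = bundles_raw[j]
        ref2d, nde, sparse, mags, temps = {}, {}, {}, {}, {}
        t_b = min(e.timestamp_s for e in entries)
        for e in entries:
            if e.role == "ref2d":
                ref2d[e.plane] = load_scan(e, base)
            elif e.role == "nondistorted_epi":
                nde[e.plane] = load_scan(e, base)
            elif e.role == "sparse_anchor":
                sparse[e.plane] = load_scan(e, base)
            elif e.role == "thermo_magnitude":
                mags.setdefault(e.plane, []).append((e.timestamp_s, load_scan(e, base)))
            elif e.role == "thermo_series":
                temps[e.plane] = load_series(base / e.path)
        bundles.append(
            SonicationBundle(
                timestamp_s=t_b,
                cell_index=j,
                ref2d=ref2d,
                thermo_magnitude={
                    p: [img for _, img in sorted(v, key=lambda x: x[0])]
                    for p, v in mags.items()
                },
                thermo_temperature=temps,
                nondistorted_epi=nde or None,
                sparse_anchor=sparse or None,
            )
        )
    plan = load_plan(base / manifest.plan_path)
    return TherapySession(
        reference_anchor=reference,
        anchor_times_s=anchor_times,
        anchors=anchors,
        bundles=bundles,
        plan=plan,
    )


def write_report(report: dict, path, provenance: dict | None = None) -> None:
    """JSON report with a provenance block (params, seeds, version)."""
    from . import __version__

    payload = dict(report)
    payload["provenance"] = {"package": "hifutrack", "version": __version__}
    if provenance:
        payload["provenance"].update(provenance)
    Path(str(path)).write_text(json.dumps(payload, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
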