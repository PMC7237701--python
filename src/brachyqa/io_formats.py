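"""Plan / structure / source / dose readers and writers.

Two dialects are supported for plans and structures: the plain structured-
text (YAML) fixture formats documented below, and DICOM (RT Plan / RT
Structure Set / RT Dose, see :mod:`brachyqa.dicom_io`).  Fixture formats
round-trip bit-exactly.

Plan fixture schema (``brachyqa-plan/1``)::

    format: brachyqa-plan/1
    source_model: toy | ir192-generic | <path>
    air_kerma_strength_U: 40700.0
    fractions: {n: 5, dose_per_fraction_gy: 5.5}   # optional
    channels:
      - id: ring
        applicator: ring | tandem | generic
        dwells:
          - {position_mm: [x, y, z], time_s: t}

Structure fixture schema (``brachyqa-struct/1``)::

    format: brachyqa-struct/1
    rois:
      - name: HR-CTV
        role: hrctv | bladder | rectum | sigmoid | applicator | other
        slices:
          - z_mm: 0.0
            polygons: [[[x, y], ...], ...]
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import Polygon as ShapelyPolygon

from .dose_engine import DoseVolume, GridSpec, ReferencePoint
from .errors import ConfigurationError, ParseError, ValidationError
from .source_model import SourceModel
from .structures_dvh import ROI, StructureSet

try:  # libyaml is much faster for the many-vertex phantom files
    from yaml import CSafeDumper as _Dumper, CSafeLoader as _Loader
except ImportError:  # pragma: no cover
    from yaml import SafeDumper as _Dumper, SafeLoader as _Loader

PLAN_FORMAT = "brachyqa-plan/1"
STRUCT_FORMAT = "brachyqa-struct/1"


@dataclass
class PlanChannel:
    """One applicator channel: ordered dwell positions (mm) and times (s)."""

    channel_id: str
    applicator_type: str
    positions_mm: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, float)
        self.times_s = np.asarray(self.times_s, float)
        if self.positions_mm.ndim != 2 or self.positions_mm.shape[1] != 3:
            raise ValidationError(f"channel {self.channel_id!r}: positions must be (n, 3)")
        if len(self.positions_mm) == 0:
            raise ValidationError(f"channel {self.channel_id!r} has no dwells")
        if self.times_s.shape != (len(self.positions_mm),):
            raise ValidationError(f"channel {self.channel_id!r}: one time per dwell required")
        if np.any(self.times_s < 0):
            raise ValidationError(f"channel {self.channel_id!r}: dwell times must be >= 0 s")


@dataclass
class PlanDocument:
    """A brachytherapy plan: channels, source strength and fractionation."""

    channels: list[PlanChannel]
    air_kerma_strength_U: float
    source_model: str
    n_fractions: int | None = None
    dose_per_fraction_gy: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("plan must contain at least one channel")
        if not self.air_kerma_strength_U > 0:
            raise ValidationError("air kerma strength S_K must be > 0 U")


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

def write_plan(plan: PlanDocument, path) -> None:
    doc = {
        "format": PLAN_FORMAT,
        "source_model": plan.source_model,
        "air_kerma_strength_U": float(plan.air_kerma_strength_U),
        "channels": [
            {
                "id": ch.channel_id,
                "applicator": ch.applicator_type,
                "dwells": [
                    {"position_mm": [float(v) for v in p], "time_s": float(t)}
                    for p, t in zip(ch.positions_mm, ch.times_s)
                ],
            }
            for ch in plan.channels
        ],
    }
    if plan.n_fractions is not None:
        doc["fractions"] = {"n": int(plan.n_fractions),
                            "dose_per_fraction_gy": float(plan.dose_per_fraction_gy)}
    if plan.metadata:
        doc["metadata"] = _jsonable(plan.metadata)
    with open(path, "w") as fh:
        yaml.dump(doc, fh, Dumper=_Dumper, default_flow_style=None, sort_keys=False)


def _detect_dialect(path, dialect: str | None, kind: str) -> str:
    if dialect is not None:
        if dialect not in (f"dicom-{kind}", "fixture-text"):
            raise ConfigurationError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = Path(path).suffix.lower()
    return f"dicom-{kind}" if suffix == ".dcm" else "fixture-text"


def read_plan(path, dialect: str | None = None) -> PlanDocument:
    """Read a plan in the fixture-text or DICOM RT Plan dialect."""
    if _detect_dialect(path, dialect, "rtplan") == "dicom-rtplan":
        from .dicom_io import read_dicom_plan
        return read_dicom_plan(path)
    try:
        with open(path) as fh:
            doc = yaml.load(fh, Loader=_Loader)
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse plan file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != PLAN_FORMAT:
        raise ParseError(f"{path} is not a {PLAN_FORMAT} document")
    missing = [k for k in ("source_model", "air_kerma_strength_U", "channels") if k not in doc]
    if missing:
        raise ParseError(f"plan file {path} missing attributes: {', '.join(missing)}")
    channels = []
    for ch in doc["channels"]:
        try:
            dwells = ch["dwells"]
            positions = [d["position_mm"] for d in dwells]
            times = [d["time_s"] for d in dwells]
            channels.append(PlanChannel(
                channel_id=str(ch["id"]), applicator_type=str(ch["applicator"]),
                positions_mm=positions, times_s=times,
            ))
        except (KeyError, TypeError) as exc:
            raise ParseError(
                f"plan file {path}: malformed channel record {ch.get('id', '?')!r} ({exc})"
            ) from exc
    fractions = doc.get("fractions") or {}
    return PlanDocument(
        channels=channels,
        air_kerma_strength_U=float(doc["air_kerma_strength_U"]),
        source_model=str(doc["source_model"]),
        n_fractions=fractions.get("n"),
        dose_per_fraction_gy=fractions.get("dose_per_fraction_gy"),
        metadata=doc.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def write_structures(ss: StructureSet, path) -> None:
    doc = {
        "format": STRUCT_FORMAT,
        "rois": [
            {
                "name": roi.name,
                "role": roi.role,
                "slices": [
                    {"z_mm": float(z),
                     "polygons": [[[float(x), float(y)] for x, y in poly] for poly in polys]}
                    for z, polys in sorted(roi.slices.items())
                ],
            }
            for roi in ss.rois.values()
        ],
    }
    with open(path, "w") as fh:
        yaml.dump(doc, fh, Dumper=_Dumper, default_flow_style=None, sort_keys=False)


def read_structures(path, dialect: str | None = None, validate: bool = True) -> StructureSet:
    """Read a structure set (fixture-text or DICOM RT Structure Set).

    With ``validate`` (default) every polygon is checked to be simple via
    shapely; a self-intersecting contour raises :class:`ValidationError`
    naming the ROI and slice.
    """
    if _detect_dialect(path, dialect, "rtstruct") == "dicom-rtstruct":
        from .dicom_io import read_dicom_structures
        ss = read_dicom_structures(path)
    else:
        try:
            with open(path) as fh:
                doc = yaml.load(fh, Loader=_Loader)
        except yaml.YAMLError as exc:
            raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
        if not isinstance(doc, dict) or doc.get("format") != STRUCT_FORMAT:
            raise ParseError(f"{path} is not a {STRUCT_FORMAT} document")
        ss = StructureSet()
        for rec in doc.get("rois", []):
            try:
                slices = {float(s["z_mm"]): [np.asarray(p, float) for p in s["polygons"]]
                          for s in rec["slices"]}
                ss.add(ROI(name=str(rec["name"]), role=str(rec.get("role", "other")),
                           slices=slices))
            except (KeyError, TypeError) as exc:
                raise ParseError(
                    f"structure file {path}: malformed ROI record {rec.get('name', '?')!r}"
                ) from exc
    if validate:
        validate_structures(ss)
    return ss


def validate_structures(ss: StructureSet) -> None:
    for roi in ss.rois.values():
        for z, polys in roi.slices.items():
            for poly in polys:
                if not ShapelyPolygon(poly).is_valid:
                    raise ValidationError(
                        f"ROI {roi.name!r} slice z={z} mm: polygon is self-intersecting"
                    )


# ---------------------------------------------------------------------------
# sources, points, doses
# ---------------------------------------------------------------------------

def load_source(name_or_path: str) -> SourceModel:
    """Resolve a source model id (``toy``, ``ir192-generic``) or table path."""
    if name_or_path in ("toy", "ir192-generic"):
        return SourceModel.packaged(name_or_path)
    p = Path(name_or_path)
    if p.exists():
        return SourceModel.from_yaml(p)
    raise ConfigurationError(f"unknown source model {name_or_path!r} (not packaged, not a file)")


def read_points(path) -> list[ReferencePoint]:
    """Reference points from YAML: ``points: [{name: ..., position_mm: [x,y,z]}, ...]``."""
    with open(path) as fh:
        doc = yaml.load(fh, Loader=_Loader)
    try:
        return [ReferencePoint(str(p["name"]), p["position_mm"]) for p in doc["points"]]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"points file {path}: expected a 'points' list of name/position_mm") from exc


def save_dose_volume(dose: DoseVolume, path) -> None:
    """Array container (.npz): values + grid + JSON metadata sidecar field."""
    np.savez_compressed(
        path,
        values=dose.values,
        origin_mm=np.asarray(dose.grid.origin_mm),
        spacing_mm=np.asarray(dose.grid.spacing_mm),
        dims=np.asarray(dose.grid.dims),
        metadata=np.frombuffer(json.dumps(_jsonable(dose.metadata)).encode(), dtype=np.uint8),
    )


def load_dose_volume(path) -> DoseVolume:
    with np.load(path) as npz:
        grid = GridSpec(origin_mm=tuple(npz["origin_mm"]), spacing_mm=tuple(npz["spacing_mm"]),
                        dims=tuple(int(d) for d in npz["dims"]))
        meta = json.loads(npz["metadata"].tobytes().decode()) if "metadata" in npz else {}
        return DoseVolume(grid=grid, values=npz["values"], metadata=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_dvh_table(results, path) -> None:
    """Delimited-text DVH export: one metrics row per structure plus curves."""
    with open(path, "w") as fh:
        fh.write("# structure\tvolume_cc\tapplicator_excluded\t"
                 "D100%\tD90%\tD10cc\tD2cc\tD0.1cc\n")
        for res in results:
            vals = [res.metrics.get(m) for m in ("D100%", "D90%", "D10cc", "D2cc", "D0.1cc")]
            cells = [f"{v:.4f}" if v is not None else "NA" for v in vals]
            fh.write(f"{res.name}\t{res.volume_cc:.6f}\t{int(res.applicator_excluded)}\t"
                     + "\t".join(cells) + "\n")
        fh.write("\n# curves: structure\tdose_cgy\tvolume_cc\tvolume_pct\n")
        for res in results:
            v0 = res.volumes_cc[0] if res.volumes_cc[0] > 0 else 1.0
            for b, v in zip(res.bins_cgy, res.volumes_cc):
                fh.write(f"{res.name}\t{b:.1f}\t{v:.6f}\t{100.0 * v / v0:.4f}\n")
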