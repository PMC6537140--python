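"""Data model and I/O for gated image stacks, plate layouts and reference decays.

Conventions
-----------
* Pixel coordinates are row-major and 0-based throughout.
* All intensities are camera digital numbers (DN); no photon conversion is
  attempted because the intensifier gain is not characterized.
* One multi-page (OME-)TIFF per field of view (FOV).  Acquisition metadata is
  stored as a JSON document in the ImageDescription tag of the first page
  under the key ``"flimhca"``.  A plain multi-page TIFF accompanied by a
  sidecar delay table (``<stem>.delays.txt``, one gate delay in ns per line,
  optionally followed by a frame role) is accepted as an equivalent dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "AcquisitionTemplate",
    "GatedStack",
    "PlateLayout",
    "WellInfo",
    "ReferenceDecay",
    "default_template",
    "read_fov_stack",
    "write_fov_stack",
    "load_plate_layout",
    "read_reference_decay",
    "write_reference_decay",
]

PREBLEACH = "prebleach"
FLIM = "flim"

_ROLES = {"query", "negative_control", "positive_control"}


class PlateIOError(ValueError):
    """Raised for malformed stacks, layouts or reference files."""


@dataclass(frozen=True)
class AcquisitionTemplate:
    """Geometry and timing of one gated acquisition sequence.

    Parameters
    ----------
    period_ns:
        Excitation repetition period T (ns).  12.5 ns for an 80 MHz source.
    gate_width_ns:
        Duration W of the intensifier gate (ns).
    delays_ns:
        Gate delay of every frame relative to the excitation pulse (ns),
        in acquisition order.
    frame_roles:
        Per-frame label, ``"prebleach"`` or ``"flim"``.  Intensity
        integration uses all frames; lifetime fitting uses flim frames only
        (prebleach frames are photobleaching transients).
    pixel_size_nm:
        Projected pixel pitch at the sample (nm).
    frame_shape:
        (rows, columns) of every frame.
    """

    period_ns: float = 12.5
    gate_width_ns: float = 4.0
    delays_ns: tuple[float, ...] = ()
    frame_roles: tuple[str, ...] = ()
    pixel_size_nm: float = 615.0
    frame_shape: tuple[int, int] = (336, 256)

    def __post_init__(self) -> None:
        if self.period_ns <= 0:
            raise PlateIOError("period_ns must be positive")
        if not (0 < self.gate_width_ns <= self.period_ns):
            raise PlateIOError("gate_width_ns must be in (0, period_ns]")
        if len(self.delays_ns) != len(self.frame_roles):
            raise PlateIOError("delays_ns and frame_roles length mismatch")
        bad = set(self.frame_roles) - {PREBLEACH, FLIM}
        if bad:
            raise PlateIOError(f"unknown frame roles: {sorted(bad)}")
        flim_d = self.flim_delays_ns
        if len(flim_d) < 3:
            raise PlateIOError(
                "need at least 3 flim frames to fit amplitude, lifetime and "
                "check residuals"
            )
        if np.any(np.diff(flim_d) <= 0):
            raise PlateIOError("flim delays must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.delays_ns)

    @property
    def flim_indices(self) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.frame_roles) if r == FLIM], dtype=int
        )

    @property
    def flim_delays_ns(self) -> np.ndarray:
        return np.asarray(self.delays_ns, dtype=float)[self.flim_indices]

    def to_dict(self) -> dict:
        return {
            "period_ns": self.period_ns,
            "gate_width_ns": self.gate_width_ns,
            "delays_ns": list(self.delays_ns),
            "frame_roles": list(self.frame_roles),
            "pixel_size_nm": self.pixel_size_nm,
            "frame_shape": list(self.frame_shape),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionTemplate":
        return cls(
            period_ns=float(d["period_ns"]),
            gate_width_ns=float(d["gate_width_ns"]),
            delays_ns=tuple(float(x) for x in d["delays_ns"]),
            frame_roles=tuple(str(r) for r in d["frame_roles"]),
            pixel_size_nm=float(d.get("pixel_size_nm", 615.0)),
            frame_shape=tuple(int(x) for x in d["frame_shape"]),
        )


#: Default FLIM gate delays (ns).  The instrument steps the 4 ns gate through
#: seven delays across the 12.5 ns period; the exact positions are a template
#: policy and every gate ends within the period (max delay + width = 12 ns).
DEFAULT_FLIM_DELAYS_NS = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


def default_template(frame_shape: tuple[int, int] = (336, 256)) -> AcquisitionTemplate:
    """The standard 12-frame sequence: 5 pre-bleach frames at zero delay
    (maximum signal, for background photobleaching) followed by 7 FLIM
    frames stepping through :data:`DEFAULT_FLIM_DELAYS_NS`."""
    delays = (0.0,) * 5 + DEFAULT_FLIM_DELAYS_NS
    roles = (PREBLEACH,) * 5 + (FLIM,) * 7
    return AcquisitionTemplate(
        delays_ns=delays, frame_roles=roles, frame_shape=tuple(frame_shape)
    )


@dataclass
class GatedStack:
    """One FOV's temporal sequence of gated intensity frames.

    ``frames`` has shape (n_frames, rows, cols), dtype float64, units DN.
    """

    frames: np.ndarray
    template: AcquisitionTemplate
    fov_id: str = ""
    well_id: str = ""
    strain_id: str = ""
    fixed_background_dn: float = 0.0
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise PlateIOError("frames must be a 3-D array (frame, row, col)")
        if self.frames.shape[0] != self.template.n_frames:
            raise PlateIOError(
                f"stack has {self.frames.shape[0]} frames but template "
                f"declares {self.template.n_frames}"
            )
        if tuple(self.frames.shape[1:]) != tuple(self.template.frame_shape):
            raise PlateIOError(
                f"frame shape {self.frames.shape[1:]} differs from template "
                f"{self.template.frame_shape}"
            )

    @property
    def flim_frames(self) -> np.ndarray:
        return self.frames[self.template.flim_indices]


@dataclass(frozen=True)
class WellInfo:
    strain_id: str
    group_id: str
    role: str


@dataclass
class PlateLayout:
    """Mapping of wells to strains, groups and control roles."""

    wells: dict[str, WellInfo]
    fovs_per_well: int = 15
    replicate_wells_per_strain: int = 3

    def __post_init__(self) -> None:
        for wid, info in self.wells.items():
            if info.role not in _ROLES:
                raise PlateIOError(f"well {wid}: unknown role {info.role!r}")
        for gid in self.group_ids:
            strains = self.group_strains(gid)
            n_neg = sum(
                1 for s in strains if self.strain_role(s) == "negative_control"
            )
            if n_neg != 1:
                raise PlateIOError(
                    f"group {gid!r} must contain exactly one negative_control "
                    f"strain (found {n_neg})"
                )

    @property
    def group_ids(self) -> list[str]:
        seen: list[str] = []
        for info in self.wells.values():
            if info.group_id not in seen:
                seen.append(info.group_id)
        return seen

    @property
    def strain_ids(self) -> list[str]:
        seen: list[str] = []
        for info in self.wells.values():
            if info.strain_id not in seen:
                seen.append(info.strain_id)
        return seen

    def strain_wells(self, strain_id: str) -> list[str]:
        return [w for w, i in self.wells.items() if i.strain_id == strain_id]

    def strain_role(self, strain_id: str) -> str:
        for info in self.wells.values():
            if info.strain_id == strain_id:
                return info.role
        raise KeyError(strain_id)

    def strain_group(self, strain_id: str) -> str:
        for info in self.wells.values():
            if info.strain_id == strain_id:
                return info.group_id
        raise KeyError(strain_id)

    def group_strains(self, group_id: str) -> list[str]:
        seen: list[str] = []
        for info in self.wells.values():
            if info.group_id == group_id and info.strain_id not in seen:
                seen.append(info.strain_id)
        return seen

    def iter_fovs(self):
        """Yield (well_id, fov_id, strain_id) for every FOV on the plate."""
        for wid, info in self.wells.items():
            for k in range(self.fovs_per_well):
                yield wid, f"{wid}_fov{k:02d}", info.strain_id


@dataclass
class ReferenceDecay:
    """Finely sampled gated decay of a dye of known monoexponential lifetime.

    The sample grid is uniform and spans one full excitation period
    (default 25 ps spacing over 12.5 ns, i.e. 500 samples).  This measurement
    carries the instrument-response information used by reference
    reconvolution.
    """

    times_ns: np.ndarray
    values: np.ndarray
    tau_ref_ns: float
    period_ns: float = 12.5

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ns.shape != self.values.shape or self.times_ns.ndim != 1:
            raise PlateIOError("times_ns and values must be equal-length 1-D")
        if self.tau_ref_ns <= 0:
            raise PlateIOError("tau_ref_ns must be positive")
        dt = np.diff(self.times_ns)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise PlateIOError("reference grid must be uniform")
        if self.times_ns[0] != 0 or self.times_ns[-1] >= self.period_ns:
            raise PlateIOError("grid must span [0, period_ns)")

    @property
    def dt_ns(self) -> float:
        return float(self.times_ns[1] - self.times_ns[0])


# ---------------------------------------------------------------------------
# Gated-stack read/write

_META_KEY = "flimhca"


def write_fov_stack(stack: GatedStack, path: str | Path) -> Path:
    """Write one FOV stack as a multi-page TIFF with JSON plane metadata."""
    path = Path(path)
    meta = {
        _META_KEY: {
            "template": stack.template.to_dict(),
            "fov_id": stack.fov_id,
            "well_id": stack.well_id,
            "strain_id": stack.strain_id,
            "fixed_background_dn": stack.fixed_background_dn,
        }
    }
    with tifffile.TiffWriter(path) as tif:
        tif.write(
            stack.frames.astype(np.float32),
            description=json.dumps(meta),
            metadata=None,
        )
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".delays.txt")


def write_sidecar_delays(
    path: str | Path, delays_ns: Sequence[float], roles: Sequence[str] | None = None
) -> Path:
    """Write a sidecar delay table next to a TIFF: one ``delay [role]`` line
    per frame, delays in ns."""
    path = _sidecar_path(Path(path))
    with open(path, "w") as fh:
        for i, d in enumerate(delays_ns):
            role = roles[i] if roles is not None else FLIM
            fh.write(f"{d:.6f} {role}\n")
    return path


def _read_sidecar(path: Path) -> tuple[list[float], list[str]]:
    delays, roles = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        delays.append(float(parts[0]))
        roles.append(parts[1] if len(parts) > 1 else FLIM)
    return delays, roles


def read_fov_stack(
    path: str | Path, template: AcquisitionTemplate | None = None
) -> GatedStack:
    """Read one FOV stack from a multi-page TIFF.

    Delay/role assignment is resolved in priority order: embedded JSON
    metadata, then a ``<name>.tif.delays.txt`` sidecar, then the supplied
    ``template``.  Frames are returned in acquisition (page) order.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        desc = tif.pages[0].description or ""
    if frames.ndim == 2:
        frames = frames[None]
    if np.any(frames < 0):
        raise PlateIOError(f"{path.name}: negative intensities on read")

    meta = None
    if desc:
        try:
            doc = json.loads(desc)
            meta = doc.get(_META_KEY)
        except (json.JSONDecodeError, AttributeError):
            meta = None

    fov_id = well_id = strain_id = ""
    fixed_bg = 0.0
    if meta is not None:
        tmpl = AcquisitionTemplate.from_dict(meta["template"])
        fov_id = meta.get("fov_id", "")
        well_id = meta.get("well_id", "")
        strain_id = meta.get("strain_id", "")
        fixed_bg = float(meta.get("fixed_background_dn", 0.0))
    elif _sidecar_path(path).exists():
        delays, roles = _read_sidecar(_sidecar_path(path))
        base = template or default_template()
        tmpl = AcquisitionTemplate(
            period_ns=base.period_ns,
            gate_width_ns=base.gate_width_ns,
            delays_ns=tuple(delays),
            frame_roles=tuple(roles),
            pixel_size_nm=base.pixel_size_nm,
            frame_shape=tuple(frames.shape[1:]),
        )
    elif template is not None:
        tmpl = template
    else:
        raise PlateIOError(
            f"{path.name}: no embedded delay metadata; supply a sidecar "
            f"delay table ({_sidecar_path(path).name}) or a template"
        )

    if frames.shape[0] != tmpl.n_frames:
        raise PlateIOError(
            f"{path.name}: {frames.shape[0]} pages but template declares "
            f"{tmpl.n_frames} frames"
        )
    for i, fr in enumerate(frames):
        if tuple(fr.shape) != tuple(tmpl.frame_shape):
            raise PlateIOError(
                f"{path.name}: frame {i} has shape {fr.shape}, expected "
                f"{tmpl.frame_shape}"
            )
    return GatedStack(
        frames=frames,
        template=tmpl,
        fov_id=fov_id,
        well_id=well_id,
        strain_id=strain_id,
        fixed_background_dn=fixed_bg,
        source_path=str(path),
    )


# ---------------------------------------------------------------------------
# Plate layout config


def load_plate_layout(path: str | Path) -> PlateLayout:
    """Load a plate layout from a YAML config.

    Expected structure::

        fovs_per_well: 15
        replicate_wells_per_strain: 3
        wells:
          A1: {strain: ndc80-donor, group: g1, role: negative_control}
          A2: {strain: ndc80-nuf2, group: g1, role: query}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "wells" not in doc:
        raise PlateIOError(f"{path}: layout config needs a 'wells' section")
    wells: dict[str, WellInfo] = {}
    for wid, entry in doc["wells"].items():
        wid = str(wid)
        if wid in wells:
            raise PlateIOError(f"{path}: duplicate well {wid}")
        wells[wid] = WellInfo(
            strain_id=str(entry["strain"]),
            group_id=str(entry.get("group", "g1")),
            role=str(entry.get("role", "query")),
        )
    return PlateLayout(
        wells=wells,
        fovs_per_well=int(doc.get("fovs_per_well", 15)),
        replicate_wells_per_strain=int(doc.get("replicate_wells_per_strain", 3)),
    )


def layout_from_strains(
    strains: Mapping[str, tuple[str, str]],
    wells_per_strain: int = 3,
    fovs_per_well: int = 15,
) -> PlateLayout:
    """Build a layout programmatically from strain -> (group, role)."""
    wells: dict[str, WellInfo] = {}
    rows = "ABCDEFGH"
    idx = 0
    for strain, (group, role) in strains.items():
        for _ in range(wells_per_strain):
            wid = f"{rows[idx // 12]}{idx % 12 + 1}"
            wells[wid] = WellInfo(strain_id=strain, group_id=group, role=role)
            idx += 1
    return PlateLayout(
        wells=wells,
        fovs_per_well=fovs_per_well,
        replicate_wells_per_strain=wells_per_strain,
    )


# ---------------------------------------------------------------------------
# Reference decay text format: '# tau_ref_ns = ...' header, two columns


def write_reference_decay(ref: ReferenceDecay, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tau_ref_ns = {ref.tau_ref_ns:.6g}\n")
        fh.write(f"# period_ns = {ref.period_ns:.6g}\n")
        fh.write("# time_ns\tvalue_dn\n")
        for t, v in zip(ref.times_ns, ref.values):
            fh.write(f"{t:.6f}\t{v:.8g}\n")
    return path


def read_reference_decay(path: str | Path) -> ReferenceDecay:
    path = Path(path)
    tau_ref = None
    period = 12.5
    times, values = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "tau_ref_ns" in line:
                tau_ref = float(line.split("=")[1])
            elif "period_ns" in line:
                period = float(line.split("=")[1])
            continue
        t, v = line.split()[:2]
        times.append(float(t))
        values.append(float(v))
    if tau_ref is None:
        raise PlateIOError(f"{path}: missing '# tau_ref_ns = ...' header")
    return ReferenceDecay(
        times_ns=np.array(times),
        values=np.array(values),
        tau_ref_ns=tau_ref,
        period_ns=period,
    )
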