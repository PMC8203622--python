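"""Readers and writers for images, coordinate frames and result tables.

Images travel as 32-bit float TIFF (pixel size in the ImageJ-style
resolution tags) or MRC/CCP4 maps (pixel size from the cell). Frames
travel as GRO (nm, read through MDAnalysis) or a simple XYZ dialect
whose comment line carries the box and time stamp. Measurement tables
are CSV with unit-bearing column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import BilayerFrame, ImageWithScale

__all__ = [
    "write_image",
    "read_image",
    "write_frame_gro",
    "write_frame_xyz",
    "read_frame",
    "DEFAULT_ROLE_MAP",
    "write_measurements_csv",
    "write_json",
]

#: atom-name -> role mapping used by the generated files
DEFAULT_ROLE_MAP: dict[str, str] = {"P": "P", "N": "N", "C": "chain", "OW": "water"}


# ---------------------------------------------------------------- images

def write_image(image: ImageWithScale, path: str | Path) -> Path:
    """Write a TIFF (.tif/.tiff) or MRC (.mrc/.map) image with scale."""
    path = Path(path)
    suffix = path.suffix.lower()
    data = image.data.astype(np.float32)
    if suffix in (".tif", ".tiff"):
        # resolution tags are pixels per unit; store nm as the unit
        res = 1.0 / image.pixel_size_nm
        tifffile.imwrite(
            path,
            data,
            resolution=(res, res),
            metadata={"unit": "nm", "pixel_size_nm": image.pixel_size_nm},
        )
    elif suffix in (".mrc", ".map"):
        import gemmi

        grid = gemmi.FloatGrid(data.shape[1], data.shape[0], 1)
        arr = np.ascontiguousarray(data.T[:, :, None])
        grid.set_unit_cell(
            gemmi.UnitCell(
                data.shape[1] * image.pixel_size_nm * 10.0,  # Angstrom
                data.shape[0] * image.pixel_size_nm * 10.0,
                image.pixel_size_nm * 10.0,
                90, 90, 90,
            )
        )
        np.asarray(grid)[:] = arr[:, :, :]
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        ccp4.write_ccp4_map(str(path))
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    return path


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> ImageWithScale:
    """Read a TIFF or MRC image; pixel size from metadata unless overridden."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            if pixel_size_nm is None:
                meta = tf.imagej_metadata or {}
                if "pixel_size_nm" in meta:
                    pixel_size_nm = float(meta["pixel_size_nm"])
                else:
                    desc = page.tags.get("ImageDescription")
                    if desc is not None:
                        try:
                            j = json.loads(desc.value)
                            pixel_size_nm = float(j.get("pixel_size_nm"))
                        except (ValueError, TypeError):
                            pixel_size_nm = None
                if pixel_size_nm is None:
                    tag = page.tags.get("XResolution")
                    # (1, 1) is tifffile's uncalibrated default, not a scale
                    if tag is not None and tag.value not in ((1, 1), (0, 0)):
                        num, den = tag.value
                        if num:
                            pixel_size_nm = den / num
    elif suffix in (".mrc", ".map"):
        import gemmi

        ccp4 = gemmi.read_ccp4_map(str(path))
        arr = np.asarray(ccp4.grid)
        data = np.ascontiguousarray(arr[:, :, 0].T)
        if pixel_size_nm is None:
            # cell a spans nx pixels, stored in Angstrom
            pixel_size_nm = ccp4.grid.unit_cell.a / ccp4.grid.nu / 10.0
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    if pixel_size_nm is None:
        raise ValueError(f"{path}: no pixel size in metadata and no override given")
    return ImageWithScale(np.asarray(data, dtype=np.float64), float(pixel_size_nm))


# ---------------------------------------------------------------- frames

def _atom_names(frame: BilayerFrame) -> list[str]:
    names = []
    chain_counter: dict[int, int] = {}
    for role, lip in zip(frame.roles, frame.lipid_index):
        if role == "P":
            names.append("P")
        elif role == "N":
            names.append("N")
        elif role == "water":
            names.append("OW")
        else:
            c = chain_counter.get(lip, 0) + 1
            chain_counter[lip] = c
            names.append(f"C{c}")
    return names


def write_frame_gro(frame: BilayerFrame, path: str | Path) -> Path:
    """Write a GRO file (positions in nm; box on the footer line)."""
    path = Path(path)
    names = _atom_names(frame)
    n = len(frame.positions)
    with open(path, "w") as fh:
        fh.write(f"synthetic bilayer frame, t= {frame.time_ns:.4f} ns\n")
        fh.write(f"{n}\n")
        for i in range(n):
            lip = frame.lipid_index[i]
            resid = (int(lip) if lip >= 0 else frame.n_lipids + i) % 99999 + 1
            resname = "LIP" if lip >= 0 else "SOL"
            x, y, z = frame.positions[i]
            fh.write(
                f"{resid:>5d}{resname:<5s}{names[i][:5]:>5s}{(i % 99999) + 1:>5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{frame.box_nm[0]:10.5f}{frame.box_nm[1]:10.5f}{frame.box_nm[2]:10.5f}\n")
    return path


def write_frame_xyz(frame: BilayerFrame, path: str | Path) -> Path:
    """Write the XYZ dialect: comment line = 'box=bx,by,bz time_ns=t';
    per-atom lines 'NAME x y z lipid_index' in nm."""
    path = Path(path)
    names = _atom_names(frame)
    with open(path, "w") as fh:
        fh.write(f"{len(frame.positions)}\n")
        b = frame.box_nm
        fh.write(f"box={b[0]:.6f},{b[1]:.6f},{b[2]:.6f} time_ns={frame.time_ns:.6f}\n")
        for i, (x, y, z) in enumerate(frame.positions):
            fh.write(
                f"{names[i]} {x:.6f} {y:.6f} {z:.6f} {int(frame.lipid_index[i])}\n"
            )
    return path


def _roles_from_names(names, role_map: dict[str, str]) -> np.ndarray:
    roles = []
    for nm in names:
        base = nm.rstrip("0123456789") or nm
        role = role_map.get(nm, role_map.get(base))
        if role is None:
            raise ValueError(f"atom name {nm!r} has no role mapping")
        roles.append(role)
    return np.asarray(roles)


def _lipid_indices_from_residues(resids, roles) -> np.ndarray:
    """Consecutive lipid numbering from residue ids; waters get -1."""
    out = np.full(len(resids), -1, dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, (rid, role) in enumerate(zip(resids, roles)):
        if role == "water":
            continue
        if rid not in mapping:
            mapping[rid] = len(mapping)
        out[i] = mapping[rid]
    return out


def read_frame(
    path: str | Path, role_map: dict[str, str] | None = None
) -> BilayerFrame:
    """Read a GRO or XYZ-dialect frame into nm coordinates."""
    path = Path(path)
    role_map = role_map or DEFAULT_ROLE_MAP
    if path.suffix.lower() == ".gro":
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        roles = _roles_from_names(u.atoms.names, role_map)
        # MDAnalysis reports Angstrom; GRO stores nm
        positions = u.atoms.positions / 10.0
        box = u.dimensions[:3] / 10.0
        # residue ids restart at 99999; rebuild by contiguous runs
        resids = _unwrap_resids(u.atoms.resids)
        lipid_idx = _lipid_indices_from_residues(resids, roles)
        time_ns = 0.0
        with open(path) as fh:
            title = fh.readline()
        if "t=" in title:
            try:
                time_ns = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        return BilayerFrame(positions, roles, lipid_idx, np.asarray(box), time_ns)
    if path.suffix.lower() == ".xyz":
        with open(path) as fh:
            n = int(fh.readline())
            comment = fh.readline().split()
            box = time_ns = None
            for tok in comment:
                if tok.startswith("box="):
                    box = np.array([float(v) for v in tok[4:].split(",")])
                elif tok.startswith("time_ns="):
                    time_ns = float(tok[8:])
            if box is None:
                raise ValueError(f"{path}: XYZ comment line lacks box=")
            names, pos, lip = [], [], []
            for _ in range(n):
                parts = fh.readline().split()
                names.append(parts[0])
                pos.append([float(v) for v in parts[1:4]])
                lip.append(int(parts[4]) if len(parts) > 4 else -1)
        roles = _roles_from_names(names, role_map)
        return BilayerFrame(
            np.asarray(pos), roles, np.asarray(lip), box, time_ns or 0.0
        )
    raise ValueError(f"unsupported frame format {path.suffix!r}")


def _unwrap_resids(resids: np.ndarray) -> np.ndarray:
    """Undo the 5-digit GRO residue-number wraparound."""
    resids = np.asarray(resids, dtype=np.int64)
    out = resids.copy()
    offset = 0
    for i in range(1, len(out)):
        if resids[i] < resids[i - 1] - 50000:
            offset += 100000
        out[i] = resids[i] + offset
    return out


# ---------------------------------------------------------------- tables

def write_measurements_csv(measurements, image_ids, path: str | Path) -> Path:
    """Thickness measurements as CSV (one row per membrane per profile)."""
    rows = []
    for image_id, mlist in zip(image_ids, measurements):
        for m in mlist:
            rows.append(
                {
                    "image_id": image_id,
                    "context": m.context,
                    "membrane_id": m.membrane_id,
                    "thickness_nm": m.thickness_nm,
                    "resolved": m.resolved,
                    "peak_positions_nm": ";".join(
                        f"{p:.4f}" for p in m.peak_positions_nm
                    ),
                }
            )
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
    return path
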