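"""File formats: HDF5 shoebox datasets, reflection tables, SHELX export,
anomalous-curve text files and a minimal PDB reader.

The dataset container holds only what DIALS-style processing would give an
analyst (counts, bounding boxes, Miller indices, orientation/scale
estimates, nominal crystal model); the simulation ground truth is written
to a separate sidecar file that the inference stages never open.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import gemmi
import h5py
import numpy as np
import pandas as pd

from .scattering import (
    AnomalousCurve,
    AtomSite,
    CrystalModel,
    EnergyGrid,
    UnitCell,
    read_curve,
    write_curve,
)
from .simulator import (
    Detector,
    GroundTruth,
    ModelError,
    MosaicModel,
    Shoebox,
    SimulatedDataset,
    Spectrum,
    StillShot,
)

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_truth",
    "read_truth",
    "reflection_table",
    "write_shelx_hkl",
    "merge_intensities",
    "read_crystal_from_pdb",
    "dataset_content_hash",
    "read_curve",
    "write_curve",
]


def _cell_tuple(cell: UnitCell) -> np.ndarray:
    return np.array([cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma])


def write_dataset(dataset: SimulatedDataset, path) -> None:
    """Write the inference-facing HDF5 container.

    Layout: /shots/<id> with orientation/scale_estimate/cell attributes and
    /shots/<id>/shoeboxes/<n> groups (counts dataset; bbox, hkl and
    metadata as attributes), plus /spectrum, /detector, /mosaic, /crystal
    and /curve groups describing the nominal forward model.
    """
    with h5py.File(path, "w") as f:
        sp = f.create_group("spectrum")
        sp.create_dataset("energies", data=dataset.spectrum.energies)
        sp.create_dataset("weights", data=dataset.spectrum.weights)
        det = f.create_group("detector")
        for k, v in (
            ("distance_mm", dataset.detector.distance_mm),
            ("pixel_size_mm", dataset.detector.pixel_size_mm),
            ("n_fast", dataset.detector.n_fast),
            ("n_slow", dataset.detector.n_slow),
            ("beam_center", np.array(dataset.detector.beam_center)),
        ):
            det.attrs[k] = v
        mos = f.create_group("mosaic")
        mos.attrs["n_domains"] = dataset.mosaic.n_domains
        mos.attrs["angular_spread_mrad"] = dataset.mosaic.angular_spread_mrad
        mos.attrs["domain_cells"] = np.array(dataset.mosaic.domain_cells)
        mos.attrs["normalize_domains"] = dataset.mosaic.normalize_domains
        cr = f.create_group("crystal")
        cr.attrs["cell"] = _cell_tuple(dataset.crystal.cell)
        atoms = dataset.crystal.atoms
        cr.create_dataset(
            "element", data=np.array([a.element for a in atoms], dtype="S4")
        )
        cr.create_dataset("frac_coords", data=np.array([a.frac_coords for a in atoms]))
        cr.create_dataset("b_factor", data=np.array([a.b_factor for a in atoms]))
        cr.create_dataset("occupancy", data=np.array([a.occupancy for a in atoms]))
        cr.create_dataset(
            "anomalous", data=np.array([a.anomalous_curve is not None for a in atoms])
        )
        curves = [a.anomalous_curve for a in atoms if a.anomalous_curve is not None]
        if curves:
            cu = f.create_group("curve")
            cu.create_dataset("energies", data=curves[0].grid.energies)
            cu.create_dataset("f_prime", data=curves[0].f_prime)
            cu.create_dataset("f_double_prime", data=curves[0].f_double_prime)
            cu.attrs["edge_energy"] = curves[0].edge_energy
        shots = f.create_group("shots")
        for shot in dataset.shots:
            g = shots.create_group(str(shot.shot_id))
            g.attrs["orientation"] = np.asarray(
                shot.metadata.get("orientation_estimate", shot.orientation)
            )
            g.attrs["scale_estimate"] = float(
                shot.metadata.get("scale_estimate", shot.scale)
            )
            g.attrs["cell"] = _cell_tuple(shot.cell)
            boxes = g.create_group("shoeboxes")
            for i, box in enumerate(shot.shoeboxes):
                bg = boxes.create_group(str(i))
                bg.create_dataset("counts", data=np.asarray(box.counts))
                bg.attrs["bbox"] = np.array(box.bbox)
                bg.attrs["hkl"] = np.array(box.hkl)
                bg.attrs["position"] = np.array(box.metadata.get("position", box.center_pixel))
                bg.attrs["resolution"] = float(box.metadata.get("resolution", np.nan))


def read_dataset(path) -> SimulatedDataset:
    """Read a dataset container; orientations/scales are the stored
    estimates (the truth lives only in the sidecar)."""
    with h5py.File(path, "r") as f:
        spectrum = Spectrum(
            energies=f["spectrum/energies"][()], weights=f["spectrum/weights"][()]
        )
        d = f["detector"].attrs
        detector = Detector(
            distance_mm=float(d["distance_mm"]),
            pixel_size_mm=float(d["pixel_size_mm"]),
            n_fast=int(d["n_fast"]),
            n_slow=int(d["n_slow"]),
            beam_center=tuple(d["beam_center"]),
        )
        m = f["mosaic"].attrs
        mosaic = MosaicModel(
            n_domains=int(m["n_domains"]),
            angular_spread_mrad=float(m["angular_spread_mrad"]),
            domain_cells=tuple(int(x) for x in m["domain_cells"]),
            normalize_domains=bool(m["normalize_domains"]),
        )
        curve = None
        if "curve" in f:
            curve = AnomalousCurve(
                grid=EnergyGrid(f["curve/energies"][()]),
                f_prime=f["curve/f_prime"][()],
                f_double_prime=f["curve/f_double_prime"][()],
                edge_energy=float(f["curve"].attrs["edge_energy"]),
            )
        cr = f["crystal"]
        cell = UnitCell(*cr.attrs["cell"])
        atoms = []
        for el, fc, b, occ, anom in zip(
            cr["element"][()],
            cr["frac_coords"][()],
            cr["b_factor"][()],
            cr["occupancy"][()],
            cr["anomalous"][()],
        ):
            atoms.append(
                AtomSite(
                    element=el.decode(),
                    frac_coords=tuple(fc),
                    b_factor=float(b),
                    occupancy=float(occ),
                    anomalous_curve=curve if anom else None,
                )
            )
        crystal = CrystalModel(cell=cell, atoms=tuple(atoms))
        shots = []
        for sid in sorted(f["shots"], key=int):
            g = f["shots"][sid]
            u = np.asarray(g.attrs["orientation"])
            scale = float(g.attrs["scale_estimate"])
            shot = StillShot(
                shot_id=int(sid),
                orientation=u,
                scale=scale,
                cell=UnitCell(*g.attrs["cell"]),
                metadata={"orientation_estimate": u, "scale_estimate": scale},
            )
            for bid in sorted(g["shoeboxes"], key=int):
                bg = g["shoeboxes"][bid]
                shot.shoeboxes.append(
                    Shoebox(
                        bbox=tuple(int(x) for x in bg.attrs["bbox"]),
                        counts=bg["counts"][()],
                        hkl=tuple(int(x) for x in bg.attrs["hkl"]),
                        metadata={
                            "shot_id": int(sid),
                            "position": tuple(bg.attrs["position"]),
                            "resolution": float(bg.attrs["resolution"]),
                            "scale_estimate": scale,
                            "orientation_estimate": u,
                        },
                    )
                )
            shots.append(shot)
    return SimulatedDataset(
        shots=shots, spectrum=spectrum, crystal=crystal, detector=detector, mosaic=mosaic
    )


def write_truth(truth: GroundTruth, path) -> None:
    """Write the ground-truth sidecar (never read by inference)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("truth")
        g.attrs["edge_shift_ev"] = truth.edge_shift_ev
        g.attrs["seed"] = truth.seed
        g.create_dataset("scales", data=truth.scales)
        g.create_dataset("orientations", data=truth.orientations)
        g.create_dataset("cells", data=np.array([_cell_tuple(c) for c in truth.cells]))
        if truth.model_error is not None:
            e = g.create_group("model_error")
            e.attrs["kind"] = truth.model_error.kind
            e.attrs["magnitude"] = truth.model_error.magnitude
            e.attrs["params"] = json.dumps(truth.model_error.params, sort_keys=True)


def read_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        g = f["truth"]
        err = None
        if "model_error" in g:
            e = g["model_error"]
            err = ModelError(
                kind=str(e.attrs["kind"]),
                magnitude=float(e.attrs["magnitude"]),
                params=json.loads(e.attrs["params"]),
            )
        cells = [UnitCell(*row) for row in g["cells"][()]]
        return GroundTruth(
            edge_shift_ev=float(g.attrs["edge_shift_ev"]),
            scales=g["scales"][()],
            orientations=g["orientations"][()],
            cells=cells,
            model_error=err,
            seed=int(g.attrs["seed"]),
        )


def dataset_content_hash(path) -> str:
    """SHA-256 over the HDF5 *content* (names, attributes, data), invariant
    to file-level metadata such as creation times."""
    h = hashlib.sha256()

    def visit(name, obj):
        h.update(name.encode())
        for k in sorted(obj.attrs):
            h.update(k.encode())
            h.update(np.asarray(obj.attrs[k]).tobytes())
        if isinstance(obj, h5py.Dataset):
            h.update(np.ascontiguousarray(obj[()]).tobytes())

    with h5py.File(path, "r") as f:
        f.visititems(visit)
    return h.hexdigest()


# --------------------------------------------------------------------------
# tables and exports


def reflection_table(dataset: SimulatedDataset) -> pd.DataFrame:
    """One row per shoebox: shot_id,h,k,l,fast,slow,sum_counts,background_est."""
    rows = []
    for shot in dataset.shots:
        for box in shot.shoeboxes:
            pos = box.metadata.get("position", box.center_pixel)
            rows.append(
                {
                    "shot_id": shot.shot_id,
                    "h": box.hkl[0],
                    "k": box.hkl[1],
                    "l": box.hkl[2],
                    "fast": pos[0],
                    "slow": pos[1],
                    "sum_counts": float(np.sum(box.counts)),
                    "background_est": box.perimeter_mean(),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["shot_id", "h", "k", "l", "fast", "slow", "sum_counts", "background_est"],
    )


def merge_intensities(dataset: SimulatedDataset) -> pd.DataFrame:
    """Background-subtracted, scale-corrected intensities merged by hkl.

    I = (sum_counts - npix * background_est) / g_est averaged over
    observations; sigma is the standard error (or sqrt(I) for singletons).
    """
    rows = []
    for shot in dataset.shots:
        g = float(shot.metadata.get("scale_estimate", shot.scale))
        for box in shot.shoeboxes:
            npix = np.asarray(box.counts).size
            rows.append(
                {
                    "h": box.hkl[0],
                    "k": box.hkl[1],
                    "l": box.hkl[2],
                    "I": (float(np.sum(box.counts)) - npix * box.perimeter_mean()) / g,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["h", "k", "l", "I", "sigma"])
    out = (
        df.groupby(["h", "k", "l"])["I"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "I", "sem": "sigma"})
    )
    out["sigma"] = np.where(
        out["count"] > 1, out["sigma"], np.sqrt(np.abs(out["I"]).clip(1.0))
    )
    return out[["h", "k", "l", "I", "sigma"]]


def write_shelx_hkl(df: pd.DataFrame, path) -> None:
    """SHELX-style fixed-width hkl file: h k l I sigma (4,4,4,8,8).

    Intensities are rescaled by a common power of ten so the strongest
    reflection fits the 8-column field, as SHELX conventions expect.
    """
    scale = 1.0
    if len(df) and np.abs(df["I"]).max() > 0:
        while np.abs(df["I"]).max() / scale >= 1e5:
            scale *= 10.0
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(
                f"{int(row.h):4d}{int(row.k):4d}{int(row.l):4d}"
                f"{row.I / scale:8.2f}{row.sigma / scale:8.2f}\n"
            )
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")  # terminator record


def read_crystal_from_pdb(
    path,
    anomalous_elements: tuple[str, ...] = ("Mn",),
    curve: Optional[AnomalousCurve] = None,
) -> CrystalModel:
    """Minimal PDB subset reader: CRYST1 + ATOM/HETATM records.

    Cartesian coordinates are converted to fractional with the CRYST1 cell;
    atoms whose element is in ``anomalous_elements`` get ``curve`` attached.
    """
    st = gemmi.read_structure(str(path))
    c = st.cell
    if c.a <= 0:
        raise ValueError("PDB file lacks a valid CRYST1 record")
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    atoms = []
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    frac = c.fractionalize(atom.pos)
                    el = atom.element.name
                    atoms.append(
                        AtomSite(
                            element=el,
                            frac_coords=(frac.x, frac.y, frac.z),
                            b_factor=float(atom.b_iso),
                            occupancy=float(atom.occ),
                            anomalous_curve=curve if el in anomalous_elements else None,
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError("no ATOM/HETATM records found")
    return CrystalModel(cell=cell, atoms=tuple(atoms))
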