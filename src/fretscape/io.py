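"""File I/O: tab-separated decay histograms and photon records, distance
restraints, AV point clouds (XYZ), and PDB structures for bead models."""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .av import AVCloud
from .core import DecayDataset, DistanceRestraint, PhotonStream, StructureModel

__all__ = [
    "write_decay", "read_decay", "write_photon_stream", "read_photon_stream",
    "write_restraints", "read_restraints", "write_xyz_cloud",
    "write_structure_pdb", "read_structure_pdb",
]


def write_decay(path, decay: DecayDataset) -> None:
    df = pd.DataFrame({"time_ns": decay.time_ns, "counts": decay.counts,
                       "irf": decay.irf_counts,
                       "donor_only": decay.donor_only_counts})
    with open(path, "w") as fh:
        fh.write(f"# background_rate\t{decay.background_rate}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_decay(path) -> DecayDataset:
    bg = 0.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# background_rate"):
            bg = float(first.split("\t")[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    return DecayDataset(df["time_ns"].to_numpy(), df["counts"].to_numpy(),
                        df["irf"].to_numpy(), df["donor_only"].to_numpy(),
                        background_rate=bg)


def write_photon_stream(path, stream: PhotonStream) -> None:
    df = pd.DataFrame({"macro_time_s": stream.macro_times,
                       "micro_time_ns": stream.micro_times,
                       "channel": stream.detector})
    with open(path, "w") as fh:
        fh.write(f"# pulse_period_ns\t{stream.pulse_period}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_photon_stream(path) -> PhotonStream:
    with open(path) as fh:
        first = fh.readline()
        period = float(first.split("\t")[1]) if first.startswith("#") else 32.0
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    return PhotonStream(df["macro_time_s"].to_numpy(),
                        df["micro_time_ns"].to_numpy(),
                        df["channel"].to_numpy(), period)


def write_restraints(path, restraints: Sequence[DistanceRestraint]) -> None:
    rows = [(r.variant, r.state, r.mean, r.uncertainty, r.lower, r.upper,
             r.convention) for r in restraints]
    pd.DataFrame(rows, columns=["variant", "state", "mean", "uncertainty",
                                "lower", "upper", "convention"]
                 ).to_csv(path, sep="\t", index=False)


def read_restraints(path) -> List[DistanceRestraint]:
    df = pd.read_csv(path, sep="\t")
    return [DistanceRestraint(r.variant, int(r.state), r.mean, r.uncertainty,
                              r.lower, r.upper, r.convention)
            for r in df.itertuples()]


def write_xyz_cloud(path, cloud: AVCloud, element: str = "D") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(cloud.points)}\n")
        fh.write(f"AV cloud, spacing {cloud.grid_spacing} A\n")
        for p in cloud.points:
            fh.write(f"{element} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")


def write_structure_pdb(path, structure: StructureModel,
                        chain: str = "A") -> None:
    """Write a bead model as CA pseudo-atoms (radius in the B-factor)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(structure)
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.chain_id = np.full(n, chain)
    atoms.res_id = structure.residue_ids
    atoms.res_name = np.full(n, "GLY")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.set_annotation("b_factor", structure.radii.astype(float))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_structure_pdb(path, name: str = None) -> StructureModel:
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(path)).get_structure(model=1,
                                                  extra_fields=["b_factor"])
    radii = np.asarray(atoms.b_factor, float)
    radii[radii <= 0] = 3.0
    return StructureModel(
        name=name or Path(path).stem,
        coords=np.asarray(atoms.coord, float),
        radii=radii,
        residue_ids=np.asarray(atoms.res_id, int))
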