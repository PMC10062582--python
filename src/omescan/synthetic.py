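"""Synthetic fixtures: toy RNA models with known 2'-O-methyl ground truth and
simulated density maps, so the whole screen is testable at desk scale.

The map simulator places an isotropic Gaussian kernel on every heavy atom
(σ = 0.425 × the nominal resolution, i.e. FWHM ≈ resolution) plus optional
i.i.d. Gaussian noise — a smooth, closed-form surrogate for an experimental
~3 Å cryo-EM map that reproduces the one feature the screen keys on: modified
riboses carry extra density at the methyl position, unmodified ones do not.

Toy residues are idealized adenosine nucleosides (heavy atoms from the wwPDB
chemical component dictionary bundled with biotite, phosphate dropped) thrown
at random positions and orientations, spatially isolated; the method probes
local density only, so chain connectivity is irrelevant to what is validated.
Truly methylated residues receive a real methyl atom built by the same
internal-coordinate geometry the screen hypothesizes, at a random clash-free
torsion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import gemmi
import numpy as np

from .density import DensityMap
from .methylation import (AdductSpec, CLASH_OVERLAP, choose_clash_free_torsion,
                          materialize_adduct, place_adduct, _scan_angles,
                          _clearance_for_positions, _frame_atoms)
from .geometry import place_internal
from .scoring import ScreenResult
from .structure import Atom, AtomicModel, Chain, Residue

__all__ = [
    "SimSpec", "GroundTruth", "RecoveryStats",
    "make_toy_rna", "simulate_map", "evaluate_recovery",
    "write_truth_tsv", "read_truth_tsv",
]

KERNEL_SIGMA_PER_RESOLUTION = 0.425   # FWHM of the atom kernel ≈ resolution
# isotropic truncation radius of the atom kernel; contributions beyond this
# are exactly zero, keeping per-atom density strictly local
_KERNEL_CUTOFF_SIGMAS = 4.0
# extra spacing guard: no two residues' heavy atoms closer than this
_MIN_INTERRESIDUE_ATOM_DIST = 4.0


@dataclass(frozen=True)
class SimSpec:
    resolution_proxy: float = 3.0        # Å; controls kernel width
    voxel_size: float = 0.5              # Å
    amplitude_mode: str = "atomic_number"  # or "uniform"
    noise_sd: float = 0.0                # map units
    padding: float = 6.0                 # Å around the model bounding box
    seed: int = 0

    def __post_init__(self):
        if self.resolution_proxy <= 0:
            raise ValueError("resolution_proxy must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_mode not in ("uniform", "atomic_number"):
            raise ValueError("amplitude_mode must be 'uniform' or 'atomic_number'")
        if self.padding < 3 * self.kernel_sigma:
            raise ValueError("padding must be at least 3 kernel sigmas")

    @property
    def kernel_sigma(self) -> float:
        return KERNEL_SIGMA_PER_RESOLUTION * self.resolution_proxy


@dataclass
class GroundTruth:
    methylated_sites: set[tuple[str, int]]
    n_candidates: int


@dataclass
class RecoveryStats:
    top_n: int
    recovered: int
    n_true: int
    falloff_pass_true: int
    falloff_pass_false: int
    mean_falloff_true: float
    mean_falloff_false: float

    def to_dict(self) -> dict:
        return {
            "top_n": self.top_n, "recovered": self.recovered, "n_true": self.n_true,
            "falloff_pass_true": self.falloff_pass_true,
            "falloff_pass_false": self.falloff_pass_false,
            "mean_falloff_true": self.mean_falloff_true,
            "mean_falloff_false": self.mean_falloff_false,
        }


def _adenosine_template() -> tuple[list[str], list[str], np.ndarray]:
    """Idealized adenosine heavy atoms (names, elements, coords) centered on O2',
    phosphate group removed."""
    from biotite.structure.info import residue as ccd_residue
    arr = ccd_residue("A")
    keep = (arr.element != "H") & ~np.isin(arr.atom_name, ("P", "OP1", "OP2", "OP3"))
    arr = arr[keep]
    names = [str(n) for n in arr.atom_name]
    elements = [str(e).capitalize() for e in arr.element]
    coords = np.asarray(arr.coord, dtype=float)
    coords = coords - coords[names.index("O2'")]
    return names, elements, coords


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_toy_rna(n_residues: int, frac_methylated: float, seed: int,
                 min_spacing: float = 8.0, spec: Optional[AdductSpec] = None,
                 max_attempts: int = 5000) -> tuple[AtomicModel, GroundTruth]:
    """Build ``n_residues`` isolated adenosines with a known methylated subset.

    Residues are placed at random positions/orientations in a box sized to the
    residue count, with every O2'-O2' pair at least ``min_spacing`` apart and
    no two residues' atoms closer than 4 Å. Exactly ``round(n · frac)``
    residues, chosen at random, receive a real methyl atom built by the adduct
    machinery at a random clash-free torsion. Bit-for-bit reproducible per
    seed. The returned model carries the methyl atoms (residue names stay the
    parent code); strip them with :func:`omescan.methylation.strip_adducts` to
    obtain the screen input.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    if not 0.0 <= frac_methylated <= 1.0:
        raise ValueError("frac_methylated must be in [0, 1]")
    if spec is None:
        spec = AdductSpec()
    model = AtomicModel()
    truth = GroundTruth(methylated_sites=set(), n_candidates=n_residues)
    if n_residues == 0:
        return model, truth

    rng = np.random.default_rng(seed)
    names, elements, template = _adenosine_template()
    box = max(min_spacing * 1.6 * n_residues ** (1 / 3) + 10.0, 2 * min_spacing)

    chain = Chain(chain_id="R")
    placed_o2: list[np.ndarray] = []
    placed_atoms: list[np.ndarray] = []
    for i in range(n_residues):
        for _ in range(max_attempts):
            origin = rng.uniform(0.0, box, size=3)
            rot = _random_rotation(rng)
            coords = template @ rot.T + origin
            if placed_o2:
                o2_ok = np.min(np.linalg.norm(np.asarray(placed_o2) - origin, axis=1)
                               ) >= min_spacing
                if not o2_ok:
                    continue
                prev = np.vstack(placed_atoms)
                d = np.linalg.norm(prev[:, None, :] - coords[None, :, :], axis=2)
                if d.min() < _MIN_INTERRESIDUE_ATOM_DIST:
                    continue
            break
        else:
            raise RuntimeError(
                f"could not place residue {i + 1}/{n_residues} with spacing "
                f"{min_spacing} Å in a {box:.0f} Å box after {max_attempts} attempts")
        res = Residue(chain_id="R", seq_id=i + 1, name="A")
        for name, element, xyz in zip(names, elements, coords):
            res.atoms.append(Atom(name=name, element=element, position=xyz))
        chain.residues.append(res)
        placed_o2.append(origin)      # template is O2'-centered
        placed_atoms.append(coords)
    model.chains.append(chain)

    n_true = int(round(n_residues * frac_methylated))
    chosen = rng.choice(n_residues, size=n_true, replace=False)
    for idx in sorted(chosen):
        res = chain.residues[idx]
        site_ref = ("R", res.seq_id)
        site = _as_site(site_ref)
        a, b, c = _frame_atoms(res, spec)
        angles = _scan_angles(step=5.0)
        positions = np.array([
            place_internal(a, b, c, spec.bond_length, spec.bond_angle, t)
            for t in angles])
        clearances = _clearance_for_positions(model, res, spec, positions)
        ok = np.flatnonzero(clearances >= -CLASH_OVERLAP)
        torsion = float(angles[rng.choice(ok)]) if len(ok) else \
            float(angles[int(np.argmax(clearances))])
        placed = place_adduct(model, site, spec, torsion)
        materialize_adduct(model, placed, spec, rename_residue=False)
        truth.methylated_sites.add(site_ref)
    return model, truth


def _as_site(ref: tuple[str, int]):
    from .structure import CandidateSite
    return CandidateSite(chain_id=ref[0], seq_id=ref[1], parent_atoms_present=True)


def simulate_map(model: AtomicModel, spec: SimSpec,
                 extra_points: Optional[list[tuple[np.ndarray, float, float]]] = None,
                 bbox: Optional[tuple[np.ndarray, np.ndarray]] = None
                 ) -> DensityMap:
    """Render a model as a density map: a Gaussian kernel per heavy atom plus
    optional i.i.d. Gaussian noise (seeded). The grid covers the model bounding
    box plus ``spec.padding`` on all sides.

    ``extra_points`` — optional (position, amplitude, sigma) triples rendered as
    additional free-standing densities; a crude emulation of unattributed map
    features such as ions sitting next to a ribose, the main false-positive
    mechanism on experimental maps. Off by default.

    ``bbox`` — optional (lo, hi) override of the model bounding box, so two
    model variants can be rendered on one common grid.
    """
    coords = model.coordinates()
    if coords.size == 0:
        raise ValueError("cannot simulate a map from an empty model")
    sigma = spec.kernel_sigma
    vx = spec.voxel_size
    if bbox is None:
        lo = coords.min(axis=0) - spec.padding
        hi = coords.max(axis=0) + spec.padding
    else:
        lo = np.asarray(bbox[0], float) - spec.padding
        hi = np.asarray(bbox[1], float) + spec.padding
    shape = np.ceil((hi - lo) / vx).astype(int) + 1
    grid = np.zeros(shape)
    axes = [lo[d] + vx * np.arange(shape[d]) for d in range(3)]

    if spec.amplitude_mode == "uniform":
        amplitudes = np.ones(len(coords))
    else:
        amplitudes = np.array([
            float(gemmi.Element(a.element).atomic_number)
            for _, a in model.iter_atoms()])

    sources = [(pos, amp, sigma) for pos, amp in zip(coords, amplitudes)]
    if extra_points:
        sources.extend((np.asarray(p, float), float(a), float(s))
                       for p, a, s in extra_points)
    for pos, amp, sig in sources:
        cutoff = _KERNEL_CUTOFF_SIGMAS * sig
        inv2s2 = 1.0 / (2.0 * sig * sig)
        sl, local = [], []
        for d in range(3):
            i0 = max(0, int(np.floor((pos[d] - cutoff - lo[d]) / vx)))
            i1 = min(shape[d] - 1, int(np.ceil((pos[d] + cutoff - lo[d]) / vx)))
            sl.append(slice(i0, i1 + 1))
            local.append(axes[d][i0:i1 + 1] - pos[d])
        dx2 = local[0][:, None, None] ** 2 + local[1][None, :, None] ** 2 \
            + local[2][None, None, :] ** 2
        grid[tuple(sl)] += np.where(dx2 <= cutoff * cutoff,
                                    amp * np.exp(-dx2 * inv2s2), 0.0)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grid += rng.normal(0.0, spec.noise_sd, size=grid.shape)
    return DensityMap(grid=grid, voxel_size=np.full(3, vx), origin=lo)


def evaluate_recovery(result: ScreenResult, truth: GroundTruth,
                      top_n: int) -> RecoveryStats:
    """Recovery@N and falloff summaries split by ground-truth label."""
    scored_refs = {r.residue_ref for r in result.records}
    excluded_refs = {s.residue_ref for s in result.excluded_sites}
    missing = truth.methylated_sites - scored_refs - excluded_refs
    if missing:
        raise ValueError(f"truth references residues absent from the screen: "
                         f"{sorted(missing)}")
    recovered = sum(1 for r in result.records
                    if r.residue_ref in truth.methylated_sites and r.rank <= top_n)
    true_f = [r.sc_falloff for r in result.records
              if r.residue_ref in truth.methylated_sites and r.sc_falloff is not None]
    false_f = [r.sc_falloff for r in result.records
               if r.residue_ref not in truth.methylated_sites and r.sc_falloff is not None]
    return RecoveryStats(
        top_n=top_n, recovered=recovered, n_true=len(truth.methylated_sites),
        falloff_pass_true=sum(1 for r in result.records
                              if r.residue_ref in truth.methylated_sites and r.falloff_pass),
        falloff_pass_false=sum(1 for r in result.records
                               if r.residue_ref not in truth.methylated_sites and r.falloff_pass),
        mean_falloff_true=float(np.mean(true_f)) if true_f else float("nan"),
        mean_falloff_false=float(np.mean(false_f)) if false_f else float("nan"),
    )


def write_truth_tsv(truth: GroundTruth, path) -> None:
    lines = ["chain\tseq_id\tlabel"]
    for chain_id, seq_id in sorted(truth.methylated_sites):
        lines.append(f"{chain_id}\t{seq_id}\tmethylated")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_tsv(path, n_candidates: Optional[int] = None) -> GroundTruth:
    """Read a known-sites table (columns: chain, seq_id[, label])."""
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("chain"):
            fh.seek(0)
        for line in fh:
            parts = line.split()
            if len(parts) >= 2:
                sites.add((parts[0], int(parts[1])))
    return GroundTruth(methylated_sites=sites,
                       n_candidates=n_candidates if n_candidates is not None else len(sites))
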