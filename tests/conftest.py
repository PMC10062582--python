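"""Shared fixtures: synthetic models/maps and a minimal raw MRC writer used to
construct header dialects (axis permutations, origin conventions) that the
package's own writer deliberately never emits."""

import numpy as np
import pytest

from omescan import (AdductSpec, ScreenConfig, SimSpec, make_toy_rna,
                     run_screen, simulate_map, strip_adducts)


def write_mrc_raw(arr, voxel, origin, perm, path, nstart=(0, 0, 0),
                  use_origin_record=True):
    """Write a float32 MRC2014 file with file axes (cols, rows, secs) mapped to
    the xyz indices given by ``perm``; origin via the ORIGIN record or via
    start indices."""
    n = arr.shape
    header = np.zeros(256, dtype=np.int32)
    fh = header.view(np.float32)
    header[0:3] = [n[perm[0]], n[perm[1]], n[perm[2]]]      # NC, NR, NS
    header[3] = 2                                           # mode 2: float32
    header[4:7] = nstart                                    # file-axis order
    header[7:10] = n                                        # MX, MY, MZ
    fh[10:13] = np.array(n) * np.array(voxel)               # cell, crystal order
    fh[13:16] = 90.0
    header[16:19] = [perm[0] + 1, perm[1] + 1, perm[2] + 1]  # MAPC, MAPR, MAPS
    fh[19], fh[20], fh[21] = arr.min(), arr.max(), arr.mean()
    header[22] = 1                                          # ISPG
    if use_origin_record:
        fh[49:52] = origin
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = int.from_bytes(bytes([0x44, 0x41, 0, 0]), "little")
    fh[54] = arr.std()
    file_arr = np.transpose(arr, (perm[2], perm[1], perm[0])).astype(np.float32)
    with open(path, "wb") as f:
        f.write(header.tobytes())
        f.write(np.ascontiguousarray(file_arr).tobytes())


def affine_map(coeffs=(2.0, 3.0, -1.0), shape=(10, 11, 12),
               voxel=(0.5, 0.5, 0.5), origin=(1.0, 2.0, 3.0)):
    """A grid sampling f(x, y, z) = a·x + b·y + c·z — trilinear is exact on it."""
    from omescan import DensityMap
    origin = np.asarray(origin, float)
    voxel = np.asarray(voxel, float)
    axes = [origin[d] + voxel[d] * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    a, b, c = coeffs
    return DensityMap(grid=a * X + b * Y + c * Z, voxel_size=voxel, origin=origin)


@pytest.fixture(scope="session")
def adduct_spec():
    return AdductSpec()


@pytest.fixture(scope="session")
def toy20(adduct_spec):
    """20 adenosines, 5 truly methylated, seed 1 — the standard small fixture."""
    model, truth = make_toy_rna(20, 0.25, seed=1, spec=adduct_spec)
    return model, truth


@pytest.fixture(scope="session")
def toy20_map(toy20):
    model, _ = toy20
    return simulate_map(model, SimSpec(resolution_proxy=3.0, noise_sd=0.0))


@pytest.fixture(scope="session")
def toy20_screen(toy20, toy20_map, adduct_spec):
    """Noise-free screen of the 20-residue fixture (refinement on)."""
    model, truth = toy20
    screen_model = strip_adducts(model, adduct_spec)
    result = run_screen(screen_model, toy20_map, adduct_spec, ScreenConfig())
    return result, truth


@pytest.fixture()
def single_nucleotide(adduct_spec):
    model, _ = make_toy_rna(1, 0.0, seed=5, spec=adduct_spec)
    return model
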