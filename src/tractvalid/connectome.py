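"""Region-to-region connection strength (SCI) and length (LCI) matrices.

The strength of cortico-cortical interconnection (SCI) between regions A and
B is the percentage of streamlines initiated in A that reach any voxel of B;
directed measurements are symmetrized by taking the maximum of the A->B and
B->A values.  The length of cortico-cortical interconnection (LCI) is, per
seeding direction, the mean over seed voxels (with at least one connecting
streamline) of the mean arc length from the seed to the first entry into the
target; the symmetric LCI takes the larger of the two directed lengths.

Distance corrections compensate the drop of streamline counts with distance:
the R-correction multiplies SCI entries by the corresponding LCI entry, the
R^2-correction by its square.  Corrected matrices are not rescaled — they are
thresholded on their own scale downstream.

A streamline "reaches" B if any of its points falls in a voxel labelled B;
for length, the arc distance to the closest such point (first entry along
either propagation sense) is used.  A streamline's own seed region does not
count as a target for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Streamline

__all__ = [
    "ConnectionMatrix",
    "SciMatrix",
    "LciMatrix",
    "directed_sci",
    "directed_lci",
    "symmetrize_max",
    "distance_correct",
    "build_matrices",
]


@dataclass(frozen=True)
class ConnectionMatrix:
    """Symmetric region-by-region matrix with named rows/columns."""

    values: np.ndarray
    region_names: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_names", list(self.region_names))
        n = len(self.region_names)
        if v.shape != (n, n):
            raise ValueError("matrix must be square and match region_names")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        self._check()

    def _check(self) -> None:
        pass

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.region_names,
                     columns=self.region_names).to_csv(path)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


class SciMatrix(ConnectionMatrix):
    """Connection strengths as percent of initiated streamlines, [0, 100]."""

    def _check(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("SCI entries must be percentages in [0, 100]")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("SCI diagonal must be zero")


class LciMatrix(ConnectionMatrix):
    """Connection lengths in mm; 0 where no connecting streamline exists."""

    def _check(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("LCI entries must be non-negative")


# ---------------------------------------------------------------------------
# Streamline -> region bookkeeping
# ---------------------------------------------------------------------------

def _visits(sl: Streamline, parcellation: np.ndarray, voxel_size: float,
            step: float) -> dict[int, float]:
    """Labels visited by a streamline and the arc distance (mm) from the seed
    to the closest visited voxel of each label."""
    shape = np.array(parcellation.shape)
    vox = np.rint(np.asarray(sl.points, dtype=float) / voxel_size).astype(int)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    if not ok.any():
        return {}
    labels = parcellation[tuple(vox[ok].T)]
    # arc distance from the seed point: consecutive points are one step apart
    dist = step * np.abs(np.arange(len(sl.points)) - sl.seed_point_index)[ok]
    out: dict[int, float] = {}
    hit = labels > 0
    for lab, d in zip(labels[hit], dist[hit]):
        lab = int(lab)
        if lab != sl.seed_region and (lab not in out or d < out[lab]):
            out[lab] = float(d)
    return out


def directed_sci(
    streamlines: list[Streamline],
    parcellation: np.ndarray,
    target_label: int,
    voxel_size: float,
    step: float,
    n_initiated: int | None = None,
) -> float:
    """Percent of initiated streamlines that reach ``target_label``."""
    n = len(streamlines) if n_initiated is None else n_initiated
    if n == 0:
        raise ValueError("no streamlines initiated")
    count = sum(
        target_label in _visits(sl, parcellation, voxel_size, step)
        for sl in streamlines
    )
    return 100.0 * count / n


def directed_lci(
    streamlines: list[Streamline],
    parcellation: np.ndarray,
    target_label: int,
    voxel_size: float,
    step: float,
) -> float:
    """Mean over seed voxels (with >= 1 connecting streamline) of the mean
    arc length from seed to first entry into the target; 0 if unconnected."""
    per_voxel: dict[int, list[float]] = {}
    for sl in streamlines:
        v = _visits(sl, parcellation, voxel_size, step)
        if target_label in v:
            per_voxel.setdefault(sl.seed_index, []).append(v[target_label])
    if not per_voxel:
        return 0.0
    return float(np.mean([np.mean(d) for d in per_voxel.values()]))


def symmetrize_max(directed: np.ndarray) -> np.ndarray:
    """Elementwise max of a directed matrix and its transpose, zero diagonal."""
    m = np.asarray(directed, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("directed matrix must be square")
    out = np.maximum(m, m.T)
    np.fill_diagonal(out, 0.0)
    return out


def distance_correct(sci: SciMatrix, lci: LciMatrix, mode: str) -> ConnectionMatrix:
    """R- or R^2-correction: SCI entries times LCI (or LCI squared).

    The output is not rescaled; acceptance thresholds for corrected matrices
    are scanned over the output's own range.
    """
    if list(sci.region_names) != list(lci.region_names) \
            or sci.values.shape != lci.values.shape:
        raise ValueError("SCI and LCI must share shape and region order")
    if mode == "R":
        values = sci.values * lci.values
    elif mode == "R2":
        values = sci.values * lci.values**2
    else:
        raise ValueError(f"unknown correction mode {mode!r} (use 'R' or 'R2')")
    return ConnectionMatrix(values, sci.region_names)


def build_matrices(
    streamlines_by_region: dict[int, list[Streamline]],
    parcellation: np.ndarray,
    voxel_size: float,
    step: float,
    region_names: dict[int, str] | None = None,
) -> tuple[SciMatrix, LciMatrix]:
    """Directed measurements for every ordered region pair, symmetrized by
    maximum (strength: max count; length: larger directed length)."""
    labels = sorted(streamlines_by_region)
    names = [region_names[l] if region_names else f"R{l}" for l in labels]
    n = len(labels)
    sci_dir = np.zeros((n, n))
    lci_dir = np.zeros((n, n))
    index = {l: i for i, l in enumerate(labels)}
    for a, sls in streamlines_by_region.items():
        ia = index[a]
        counts = np.zeros(n)
        per_voxel: list[dict[int, list[float]]] = [dict() for _ in range(n)]
        for sl in sls:
            v = _visits(sl, parcellation, voxel_size, step)
            for lab, d in v.items():
                if lab in index:
                    ib = index[lab]
                    counts[ib] += 1
                    per_voxel[ib].setdefault(sl.seed_index, []).append(d)
        sci_dir[ia] = 100.0 * counts / max(len(sls), 1)
        for ib in range(n):
            if per_voxel[ib]:
                lci_dir[ia, ib] = np.mean(
                    [np.mean(dd) for dd in per_voxel[ib].values()]
                )
    sci = SciMatrix(symmetrize_max(sci_dir), names)
    lci = LciMatrix(symmetrize_max(lci_dir), names)
    return sci, lci
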