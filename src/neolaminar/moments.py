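"""Central moments of intracortical intensity profiles and aggregations.

A depth profile is treated as a histogram: the 12 intracortical depths
are the bins (indexed 1..12, 1 = pial, 12 = white) and the sampled
intensities are the frequencies.  The first moment, the *center of
gravity* mu1, is the mean of that depth distribution — larger values
mean the myelin-sensitive signal is balanced towards the deeper cortex.
The second moment mu2 is the standard deviation of the depth
distribution; it is maximal for a perfectly flat (homogeneous) profile
and zero when all intensity concentrates at a single depth.  By
convention the second moment is *called* "variance" in the
microstructure-profiling literature although it is reported on the
standard-deviation scale; that naming is kept here.

Both moments are invariant to multiplying a profile by a positive
constant, which makes them insensitive to the global intensity scaling
(transmit-field bias) of ratio images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateProfileError, EmptyResultError

__all__ = [
    "Parcellation",
    "profile_moments",
    "parcel_mean_profiles",
    "sliding_window_profiles",
    "moment_sorted_bins",
]


@dataclass
class Parcellation:
    """Per-vertex parcel labels plus the set of excluded parcel ids."""

    labels: np.ndarray
    excluded_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.excluded_ids = frozenset(int(i) for i in self.excluded_ids)

    @property
    def parcel_ids(self) -> np.ndarray:
        """All distinct labels, sorted."""
        return np.unique(self.labels)

    @property
    def analyzed_ids(self) -> np.ndarray:
        """Distinct labels not excluded from analysis."""
        ids = self.parcel_ids
        return ids[~np.isin(ids, list(self.excluded_ids))]


def profile_moments(profile):
    """Center of gravity and depth spread of one or many profiles.

    Parameters
    ----------
    profile : (D,) or (n, D) nonnegative array
        Depth profiles, pial to white.

    Returns
    -------
    mu1, mu2 : floats or (n,) arrays
        mu1 in [1, D] (depth-index units), mu2 = sqrt of the weighted
        depth variance, in the same units.

    Raises
    ------
    DegenerateProfileError
        On negative entries or an all-zero profile.
    """
    p = np.asarray(profile, dtype=np.float64)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if np.any(p < 0):
        raise DegenerateProfileError("profiles must be nonnegative")
    total = p.sum(axis=1)
    if np.any(total <= 0):
        raise DegenerateProfileError("all-zero profile has undefined moments")
    depths = np.arange(1, p.shape[1] + 1, dtype=np.float64)
    w = p / total[:, None]
    mu1 = w @ depths
    mu2 = np.sqrt(np.einsum("nd,nd->n", w, (depths[None, :] - mu1[:, None]) ** 2))
    if single:
        return float(mu1[0]), float(mu2[0])
    return mu1, mu2


def parcel_mean_profiles(
    intensities: np.ndarray,
    parcellation: Parcellation,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Average vertex profiles within each analyzed parcel.

    Vertices masked out (invalid samples) are ignored; a parcel with no
    valid vertex is omitted.  Returns a DataFrame indexed by parcel id
    with the D depth columns plus ``n_vertices``.
    """
    intensities = np.asarray(intensities, dtype=np.float64)
    if mask is None:
        mask = np.ones(len(intensities), dtype=bool)
    rows = {}
    for pid in parcellation.analyzed_ids:
        sel = (parcellation.labels == pid) & mask
        if not sel.any():
            continue
        rows[int(pid)] = np.concatenate(
            [intensities[sel].mean(axis=0), [sel.sum()]]
        )
    if not rows:
        raise EmptyResultError("no analyzed parcel has valid vertices")
    n_depths = intensities.shape[1]
    cols = [f"depth_{d}" for d in range(1, n_depths + 1)] + ["n_vertices"]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "parcel_id"
    return out


def sliding_window_profiles(
    subject_profiles: np.ndarray,
    ages: np.ndarray,
    width: float = 1.5,
    overlap: float = 0.5,
):
    """Mean profiles within sliding age windows.

    Windows start at the youngest age and advance by ``width * (1 -
    overlap)`` weeks; each window averages the profiles of subjects whose
    age falls in ``[start, start + width)``.  Empty windows are dropped.

    Returns
    -------
    window_profiles : (W, D) array
    window_centers : (W,) array of window-centre ages (weeks)
    """
    profiles = np.asarray(subject_profiles, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if len(profiles) == 0:
        raise EmptyResultError("no subjects")
    if width <= 0 or not (0 <= overlap < 1):
        raise ValueError("need width > 0 and overlap in [0, 1)")
    step = width * (1.0 - overlap)
    start = ages.min()
    means, centers = [], []
    while start <= ages.max():
        sel = (ages >= start) & (ages < start + width)
        if sel.any():
            means.append(profiles[sel].mean(axis=0))
            centers.append(start + width / 2.0)
        start += step
    return np.asarray(means), np.asarray(centers)


def moment_sorted_bins(
    profiles: np.ndarray, which_moment: str = "mu1", n_bins: int = 100
) -> np.ndarray:
    """Sort profiles by a moment and average within rank bins.

    All profiles (across subjects and regions) are ranked by the chosen
    moment and partitioned, in rank order, into ``n_bins`` near-equal
    groups; each group is averaged per depth.  This is the display
    reduction used to visualise how profile shape varies systematically
    with each moment.
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.size == 0:
        raise EmptyResultError("no profiles to bin")
    if which_moment not in ("mu1", "mu2"):
        raise ValueError("which_moment must be 'mu1' or 'mu2'")
    mu1, mu2 = profile_moments(profiles)
    key = mu1 if which_moment == "mu1" else mu2
    order = np.argsort(key, kind="stable")
    groups = np.array_split(order, n_bins)
    return np.asarray([profiles[g].mean(axis=0) for g in groups if len(g)])
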