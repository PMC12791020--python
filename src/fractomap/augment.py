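"""Balanced training-set construction from marker profiles.

Marker classes are rarely balanced (lipid droplets may have a handful of
markers, mitochondria hundreds), and real datasets contain species shared
between compartments for which no annotated training examples exist. Two
augmentation steps address this, per replicate:

* **upsampling** — every compartment is filled up to the size of the
  largest marker class (``N_max``) with artificial profiles: the
  fraction-wise median of three randomly drawn reference profiles plus
  Gaussian noise with twice the fraction-wise s.d. of the drawn profiles,
  clipped at zero and renormalized to sum 1;
* **mixing** — two-compartment convex combinations at 25:75, 50:50 and
  75:25 ratios, 5% of ``N_max`` new profiles per ratio per compartment,
  labelled with the mixing ratio as the target weight vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DataError, MarkerSet
from .preprocess import ProfileTensor

MIX_RATIOS = (0.25, 0.5, 0.75)


@dataclass
class TrainingSet:
    """Profiles with compartment-weight targets for one replicate."""

    X: np.ndarray          # (n, F) profiles, rows sum to 1
    Y: np.ndarray          # (n, C) weight targets, rows sum to 1
    origin: np.ndarray     # (n,) in {"marker", "upsampled", "mixed"}
    compartment_order: list

    def __len__(self) -> int:
        return self.X.shape[0]


def upsample_compartment(markers: np.ndarray, n_new: int,
                         rng: np.random.Generator,
                         noise_factor: float = 2.0) -> np.ndarray:
    """Generate ``n_new`` artificial profiles for one compartment.

    ``markers`` is an (m, F) array of reference profiles (rows sum to 1);
    each artificial profile is the fraction-wise median of three randomly
    chosen rows plus N(0, (noise_factor*sigma_f)^2) noise, where sigma_f is
    the fraction-wise s.d. of the three chosen rows, then clipped at zero
    and renormalized.
    """
    markers = np.asarray(markers, dtype=float)
    if markers.shape[0] < 3:
        raise DataError(
            f"upsampling needs >= 3 reference profiles, got {markers.shape[0]}"
        )
    if n_new <= 0:
        return np.empty((0, markers.shape[1]))
    idx = rng.integers(0, markers.shape[0], size=(n_new, 3))
    trips = markers[idx]                      # (n_new, 3, F)
    base = np.median(trips, axis=1)
    sigma = trips.std(axis=1, ddof=0)
    noised = base + rng.normal(0.0, 1.0, size=base.shape) * noise_factor * sigma
    noised = np.clip(noised, 0.0, None)
    sums = noised.sum(axis=1, keepdims=True)
    # a fully zeroed draw falls back to its (nonnegative) base profile
    dead = sums[:, 0] <= 0
    if dead.any():
        noised[dead] = base[dead]
        sums = noised.sum(axis=1, keepdims=True)
    return noised / sums


def mix_profiles(profiles_a: np.ndarray, profiles_b: np.ndarray,
                 ratio: float, n_new: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Convex combinations ``ratio*a + (1-ratio)*b`` of randomly drawn rows.

    Returns (profiles, weights) where weights is ``(n_new, 2)`` holding
    ``(ratio, 1-ratio)`` for the (a, b) compartments.
    """
    if ratio not in MIX_RATIOS:
        raise DataError(f"mix ratio must be one of {MIX_RATIOS}, got {ratio}")
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    ia = rng.integers(0, a.shape[0], size=n_new)
    ib = rng.integers(0, b.shape[0], size=n_new)
    mixed = ratio * a[ia] + (1.0 - ratio) * b[ib]
    weights = np.tile([ratio, 1.0 - ratio], (n_new, 1))
    return mixed, weights


def build_training_set(profiles: ProfileTensor, markers: MarkerSet,
                       condition, replicate, seed: int,
                       mix_ratios=MIX_RATIOS, mix_fraction: float = 0.05,
                       noise_factor: float = 2.0) -> TrainingSet:
    """Assemble the balanced training set for one (condition, replicate).

    Original marker profiles + upsampling of every class to ``N_max``
    (size of the largest class) + ``round(mix_fraction * N_max)`` mixed
    profiles per ratio per compartment, the partner compartment drawn
    uniformly at random per generated profile.
    """
    rng = np.random.default_rng(seed)
    mat = profiles.profiles[(condition, replicate)]
    order = markers.compartment_order
    C = len(order)
    per_class: dict = {}
    for c in order:
        ids = [s for s in markers.species_of(c) if s in mat.index]
        per_class[c] = mat.loc[ids].to_numpy(dtype=float)
    n_max = max(arr.shape[0] for arr in per_class.values())

    X, Y, origin = [], [], []
    pool = {}
    for ci, c in enumerate(order):
        arr = per_class[c]
        onehot = np.zeros(C)
        onehot[ci] = 1.0
        X.append(arr)
        Y.append(np.tile(onehot, (arr.shape[0], 1)))
        origin += ["marker"] * arr.shape[0]
        ups = upsample_compartment(arr, n_max - arr.shape[0], rng,
                                   noise_factor=noise_factor)
        X.append(ups)
        Y.append(np.tile(onehot, (ups.shape[0], 1)))
        origin += ["upsampled"] * ups.shape[0]
        pool[c] = np.vstack([arr, ups])

    n_mix = round(mix_fraction * n_max)
    for ci, c in enumerate(order):
        others = [k for k in range(C) if k != ci]
        for ratio in mix_ratios:
            partners = rng.choice(others, size=n_mix)
            for k in partners:
                mixed, w = mix_profiles(pool[c], pool[order[k]], ratio, 1, rng)
                target = np.zeros(C)
                target[ci], target[k] = w[0]
                X.append(mixed)
                Y.append(target[None, :])
                origin.append("mixed")

    return TrainingSet(
        X=np.vstack(X), Y=np.vstack(Y),
        origin=np.asarray(origin, dtype=object),
        compartment_order=list(order),
    )
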