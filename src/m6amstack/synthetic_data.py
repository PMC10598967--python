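"""Synthetic labeled window datasets with a planted position-specific motif.

Positives and negatives are both forced to carry 'A' at the center (so the
center itself is uninformative, as in the real benchmark); positives draw
the configured offsets from an effect-interpolated emission distribution,
everything else from the background.  ``effect=0`` makes the two classes
distributionally identical — the null used for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import Label, LabeledDataset, SiteWindow

__all__ = ["MotifModel", "generate_dataset", "default_benchmark_surrogate",
           "default_motif", "surrogate_motif"]

BASES = "ACGU"
UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class MotifModel:
    """Planted motif: per-offset emission distributions, blended with the
    background by `effect` (0 = pure background, 1 = pure emission)."""

    offsets: tuple[int, ...]
    emission: tuple[tuple[float, float, float, float], ...]
    effect: float = 1.0

    def __post_init__(self):
        if len(self.offsets) != len(self.emission):
            raise ValueError("offsets and emission rows must align")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must be in [0, 1]")
        for row in self.emission:
            if abs(sum(row) - 1.0) > 1e-9 or min(row) < 0:
                raise ValueError(f"emission row {row} is not a distribution")
        if 0 in self.offsets:
            raise ValueError("offset 0 is the forced-A center; not plantable")


_G_RICH = (0.02, 0.08, 0.82, 0.08)
_C_RICH = (0.02, 0.82, 0.08, 0.08)
_U_RICH = (0.02, 0.08, 0.08, 0.82)
_ROTATION = (_G_RICH, _C_RICH, _U_RICH)


def default_motif(effect: float = 1.0) -> MotifModel:
    """G/C/U-enriched positions immediately downstream of the center."""
    offsets = (1, 2, 3, 4, 5)
    emission = tuple(_ROTATION[i % 3] for i in range(len(offsets)))
    return MotifModel(offsets=offsets, emission=emission, effect=effect)


def surrogate_motif(effect: float = 0.5) -> MotifModel:
    """Wider motif used by the benchmark surrogate: enriched flanks on both
    sides of the center (C/U-heavy upstream, G/C/U-heavy downstream)."""
    offsets = tuple(o for o in range(-8, 9) if o != 0)
    emission = tuple(_ROTATION[i % 3] for i in range(len(offsets)))
    return MotifModel(offsets=offsets, emission=emission, effect=effect)


def _validate_background(background) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or bg.min() < 0:
        raise ValueError(f"background {background} is not a distribution over "
                         f"{BASES}")
    return bg


def generate_dataset(n_pos: int, n_neg: int, delta: int = 20,
                     motif: MotifModel | None = None,
                     background=UNIFORM, seed: int = 0) -> LabeledDataset:
    """Draw `n_pos` motif-bearing and `n_neg` background windows."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("sample counts must be non-negative")
    bg = _validate_background(background)
    motif = motif or default_motif()
    L = 2 * delta + 1
    for off in motif.offsets:
        if not -delta <= off <= delta:
            raise ValueError(f"offset {off} outside window half-width {delta}")
    rng = np.random.default_rng(seed)

    def draw(n: int, positive: bool) -> list[str]:
        if n == 0:
            return []
        probs = np.tile(bg, (L, 1))
        if positive:
            for off, emis in zip(motif.offsets, motif.emission):
                row = delta + off
                probs[row] = (1.0 - motif.effect) * bg \
                    + motif.effect * np.asarray(emis)
        cum = probs.cumsum(axis=1)
        u = rng.random((n, L))
        idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        idx[:, delta] = 0  # force center 'A' in both classes
        lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
        return [s.decode() for s in lut[idx].view(f"S{L}").ravel()]

    windows = []
    for seq_idx, seq in enumerate(draw(n_pos, True)):
        windows.append(SiteWindow(f"pos_{seq_idx}", delta + 1, delta, seq,
                                  Label.POSITIVE))
    for seq_idx, seq in enumerate(draw(n_neg, False)):
        windows.append(SiteWindow(f"neg_{seq_idx}", delta + 1, delta, seq,
                                  Label.NEGATIVE))
    return LabeledDataset(windows)


@dataclass(frozen=True)
class SurrogateBenchmark:
    train: LabeledDataset
    test: LabeledDataset


def default_benchmark_surrogate(seed: int = 0, effect: float = 0.5
                                ) -> SurrogateBenchmark:
    """A stand-in with the benchmark's shape: 1419/1419 training and 355/355
    test windows at delta=20, moderate-effect multi-offset motif."""
    motif = surrogate_motif(effect=effect)
    train = generate_dataset(1419, 1419, delta=20, motif=motif, seed=seed)
    test = generate_dataset(355, 355, delta=20, motif=motif, seed=seed + 1)
    return SurrogateBenchmark(train=train, test=test)
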