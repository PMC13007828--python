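"""Bipolar re-referencing of 10-20 scalp electrodes.

The default montage pairs each of 12 neonatal-adapted 10-20 electrodes with
its spatial neighbors (parasagittal chains, temporal chains, and transverse
links), yielding 24 bipolar derivations. The exact neighbor graph is a
configuration concern: any pair list can be supplied via
:meth:`BipolarMontage.from_yaml` or the constructor.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .recording import Annotation, Recording

#: 12 scalp electrodes of the reduced neonatal 10-20 array.
DEFAULT_ELECTRODES = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4",
    "P3", "P4", "O1", "O2", "T3", "T4",
)

# Neighbor graph over the 12-electrode array: left/right parasagittal
# chains, left/right temporal chains with fronto/parieto-temporal links,
# and transverse pairs (including the transverse temporal pair), giving
# exactly 24 unordered neighbor pairs.
DEFAULT_PAIRS = (
    # parasagittal chains
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    # temporal chains
    ("Fp1", "T3"), ("T3", "O1"),
    ("Fp2", "T4"), ("T4", "O2"),
    # temporal-to-parasagittal links
    ("T3", "F3"), ("T3", "C3"), ("T3", "P3"),
    ("T4", "F4"), ("T4", "C4"), ("T4", "P4"),
    # transverse pairs
    ("Fp1", "Fp2"), ("F3", "F4"), ("C3", "C4"),
    ("P3", "P4"), ("O1", "O2"), ("T3", "T4"),
)


class MontageError(ValueError):
    """Raised when a montage cannot be applied to a recording."""


@dataclass(frozen=True)
class BipolarMontage:
    """Ordered list of (anode, cathode) electrode pairs."""

    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS

    def __post_init__(self) -> None:
        seen = set()
        for a, c in self.pairs:
            if a == c:
                raise ValueError(f"pair members must differ, got ({a}, {c})")
            key = frozenset((a, c))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({a}, {c})")
            seen.add(key)

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]

    @property
    def electrodes(self) -> set[str]:
        return {e for pair in self.pairs for e in pair}

    @classmethod
    def from_yaml(cls, path) -> "BipolarMontage":
        """Load a pair list from YAML: ``pairs: [[Fp1, F3], ...]``."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        pairs = tuple((str(a), str(c)) for a, c in doc["pairs"])
        return cls(pairs=pairs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"pairs": [list(p) for p in self.pairs]}, fh)


def build_bipolar(recording: Recording, montage: BipolarMontage | None = None) -> Recording:
    """Re-reference to bipolar channels: output i = anode_i - cathode_i.

    Annotations propagate; a ``bad_channel`` annotation on either member
    electrode marks the derived bipolar channel bad. Global annotations
    (sleep, ictal) carry over unchanged.
    """
    montage = montage or BipolarMontage()
    missing = sorted(montage.electrodes - set(recording.channel_labels))
    if missing:
        raise MontageError(f"electrodes missing from recording: {missing}")

    rows = []
    for anode, cathode in montage.pairs:
        rows.append(recording.channel(anode) - recording.channel(cathode))

    annotations: list[Annotation] = []
    for ann in recording.annotations:
        if ann.channel is None:
            annotations.append(ann)
            continue
        # map electrode-level annotation onto every pair containing it
        for (a, c), label in zip(montage.pairs, montage.labels):
            if ann.channel in (a, c):
                annotations.append(
                    Annotation(ann.label, label, ann.start_s, ann.end_s)
                )

    import numpy as np

    return Recording(
        samples=np.vstack(rows),
        fs=recording.fs,
        channel_labels=montage.labels,
        annotations=annotations,
    )
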