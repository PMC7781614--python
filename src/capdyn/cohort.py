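"""Core in-memory containers for component-space fMRI cohorts.

After group ICA, each subject's resting-state scan is reduced to a
frames x components matrix of component time courses. Downstream CAP
analysis operates entirely in this component space: a designated seed
component (salience / midcingulo-insular network) drives frame
selection, and only components flagged as non-noise enter clustering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: 12-network vocabulary used to label components.
DEFAULT_NETWORKS: tuple[str, ...] = (
    "salience",
    "default_mode",
    "central_executive",
    "frontal",
    "parietal",
    "sensorimotor",
    "subcortical",
    "temporal",
    "occipital",
    "attention",
    "cerebellum",
    "auditory",
)

HANDEDNESS_LEVELS: tuple[str, ...] = ("right", "left", "ambidextrous")


class CohortSchemaError(ValueError):
    """Raised when cohort inputs violate the expected schema."""


@dataclass(frozen=True)
class ComponentTimeSeries:
    """One subject's frames x components matrix with component metadata.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray, shape (T, C)
        Component time courses, one column per component (arbitrary units).
    tr_seconds : float
        Repetition time of the acquisition in seconds.
    component_ids : tuple of str
        One label per column of ``data``.
    noise_flags : ndarray of bool, shape (C,)
        True for components judged to be artifactual (motion, CSF, ...);
        only non-noise components enter CAP clustering.
    network_labels : tuple of str
        Network membership of each component.
    seed_component : str
        Id of the seed component whose high-activation frames are selected.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    component_ids: tuple[str, ...]
    noise_flags: np.ndarray
    network_labels: tuple[str, ...]
    seed_component: str

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "component_ids", tuple(self.component_ids))
        object.__setattr__(self, "network_labels", tuple(self.network_labels))
        object.__setattr__(
            self, "noise_flags", np.asarray(self.noise_flags, dtype=bool)
        )
        if data.ndim != 2:
            raise CohortSchemaError(
                f"{self.subject_id}: data must be 2-D (frames x components)"
            )
        t, c = data.shape
        if t < 2 or c < 1:
            raise CohortSchemaError(
                f"{self.subject_id}: need >= 2 frames and >= 1 component, "
                f"got {t} x {c}"
            )
        if not np.all(np.isfinite(data)):
            raise CohortSchemaError(f"{self.subject_id}: data contains non-finite values")
        if self.tr_seconds <= 0:
            raise CohortSchemaError(f"{self.subject_id}: tr_seconds must be positive")
        if len(self.component_ids) != c or len(self.network_labels) != c:
            raise CohortSchemaError(
                f"{self.subject_id}: component metadata length does not match "
                f"{c} columns"
            )
        if self.noise_flags.shape != (c,):
            raise CohortSchemaError(f"{self.subject_id}: noise_flags must have shape ({c},)")
        if len(set(self.component_ids)) != c:
            raise CohortSchemaError(f"{self.subject_id}: duplicate component ids")
        if self.seed_component not in self.component_ids:
            raise CohortSchemaError(
                f"{self.subject_id}: seed component {self.seed_component!r} "
                "not among component ids"
            )
        if self.noise_flags[self.seed_index]:
            raise CohortSchemaError(
                f"{self.subject_id}: seed component must be flagged non-noise"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    @property
    def seed_index(self) -> int:
        return self.component_ids.index(self.seed_component)

    @property
    def seed_series(self) -> np.ndarray:
        """The seed component's time course, shape (T,)."""
        return self.data[:, self.seed_index]

    def with_data(self, data: np.ndarray) -> "ComponentTimeSeries":
        """Return a copy carrying ``data`` but identical metadata."""
        return dataclasses.replace(self, data=np.asarray(data, dtype=float))
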