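"""Study design and quantile-summary types shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

#: The two maturity classes, in fixed order (reference class first).
STAGES: tuple[str, str] = ("half-red", "red")


@dataclass(frozen=True)
class QuantileSpec:
    """Median and 5th/95th percentile summary of a feature in one stage.

    This is the unit in which the study system is tabulated: each sensor or
    colour feature is summarised per maturity stage as ``median [p5–p95]``.
    """

    median: float
    p5: float
    p95: float

    def __post_init__(self) -> None:
        if not (self.p5 <= self.median <= self.p95):
            raise ValueError(
                f"quantiles must satisfy p5 <= median <= p95, got "
                f"({self.p5}, {self.median}, {self.p95})"
            )

    @property
    def sd(self) -> float:
        """Normal-scale spread implied by the 5th–95th span: (p95-p5)/3.29."""
        return (self.p95 - self.p5) / 3.29


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the two-stage, three-harvest strawberry study.

    Each maturity stage is sampled at ``n_harvests`` harvest times with
    ``samples_per_stage_per_harvest`` pooled biological samples per harvest.
    Technical replication differs per modality: 11 e-nose runs, 5 FTIR
    spectra and 8 image acquisitions per sample.  FTIR pools the fruit of a
    whole harvest, so it has one sample per (stage, harvest).
    """

    n_harvests: int = 3
    samples_per_stage_per_harvest: int = 4
    stages: tuple[str, str] = STAGES
    reps_enose: int = 11
    reps_ftir: int = 5
    reps_image: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_harvests,
            self.samples_per_stage_per_harvest,
            self.reps_enose,
            self.reps_ftir,
            self.reps_image,
        )
        if any(int(c) != c or c < 1 for c in counts):
            raise ValueError("all design counts must be integers >= 1")
        if len(self.stages) != 2 or len(set(self.stages)) != 2:
            raise ValueError("exactly two distinct stages are required")

    @property
    def n_samples_per_stage(self) -> int:
        return self.n_harvests * self.samples_per_stage_per_harvest

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_stage

    @property
    def n_obs_enose(self) -> int:
        """Total e-nose observations (samples x technical replicates)."""
        return self.n_samples * self.reps_enose

    @property
    def n_obs_ftir(self) -> int:
        """FTIR observations: one pooled sample per (stage, harvest)."""
        return 2 * self.n_harvests * self.reps_ftir

    @property
    def n_obs_image(self) -> int:
        return self.n_samples * self.reps_image

    def iter_samples(self):
        """Yield (stage, harvest, sample_id) for every biological sample."""
        for stage in self.stages:
            for h in range(1, self.n_harvests + 1):
                for s in range(1, self.samples_per_stage_per_harvest + 1):
                    yield stage, f"H{h}", f"{stage}_H{h}_S{s}"

    def iter_ftir_samples(self):
        """Yield (stage, harvest, sample_id) for the pooled FTIR samples."""
        for stage in self.stages:
            for h in range(1, self.n_harvests + 1):
                yield stage, f"H{h}", f"{stage}_H{h}_pool"
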