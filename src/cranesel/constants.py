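"""Study-design constants for the wintering-crane habitat-selection analysis.

These are the fixed quantities of the study design: the diel windows that
separate daytime foraging/loafing from nocturnal river roosting, the
movement-based availability radius, the 1:50 used:available matching ratio,
and the radii used for structure-density and bank-vegetation covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class StudyConstants:
    """Constants governing the used-available design.

    Attributes
    ----------
    diurnal_start, diurnal_end : float
        Clock hours delimiting the diurnal window [07:00, 18:00).
    migration_distance_cap_m : float
        Steps at or above this length (m) are treated as migratory
        arrivals/departures and excluded from the movement-radius estimate.
    step_elapsed_max_hr : float
        Steps with more elapsed time than this between successive fixes are
        excluded (default variant keeps steps with elapsed <= 3 h).
    availability_radius_m : float
        Radius of the availability disc around each used location (m); the
        study's mean maximum movement distance, 6.7 km.
    n_available : int
        Available (control) locations matched to each used location.
    density_radii_m : tuple
        Radii (m) at which human-structure density is counted.
    stretch_radii_m : tuple
        Along-river stretch lengths (m) over which bank vegetation height
        is averaged.
    flight_altitude_threshold_m : float
        Altitude above ground (m) beyond which a fix is classified as
        flying and excluded from both periods.
    cv_train_frac : float
        Fraction of strata used for training in each cross-validation
        replicate.
    cv_reps : int
        Number of cross-validation replicates.
    vif_threshold : float
        Variance-inflation-factor threshold at or above which a covariate
        is dropped from a model.
    """

    diurnal_start: float = 7.0
    diurnal_end: float = 18.0
    migration_distance_cap_m: float = 10_000.0
    step_elapsed_max_hr: float = 3.0
    availability_radius_m: float = 6_700.0
    n_available: int = 50
    density_radii_m: tuple = (100.0, 500.0, 1000.0)
    stretch_radii_m: tuple = (100.0, 500.0, 1000.0)
    flight_altitude_threshold_m: float = 50.0
    cv_train_frac: float = 0.8
    cv_reps: int = 1000
    vif_threshold: float = 5.0

    def __post_init__(self):
        for name in (
            "migration_distance_cap_m",
            "step_elapsed_max_hr",
            "availability_radius_m",
            "n_available",
            "flight_altitude_threshold_m",
            "cv_train_frac",
            "vif_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


#: The seven daily GPS fix times (clock hours); 24.0 denotes midnight and is
#: canonicalized to 00:00 of the following day when timestamps are built.
FIX_SCHEDULE_HOURS = (7.0, 8.0, 10.0, 14.0, 16.0, 18.0, 24.0)

#: Bi-monthly winter periods used for the river surface-water composites.
PERIODS = ("oct-nov", "dec-jan", "feb-mar")


def period_of_month(month: int) -> str:
    """Map a calendar month to its bi-monthly winter period."""
    if month in (10, 11):
        return "oct-nov"
    if month in (12, 1):
        return "dec-jan"
    if month in (2, 3):
        return "feb-mar"
    raise ConfigurationError(f"month {month} is outside the winter study window")
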