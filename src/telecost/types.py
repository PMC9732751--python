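"""Domain types for the two-arm telemedicine cost and emission analysis.

The analysis compares a telemedicine arm (video consultation at home) with a
control arm (conventional in-clinic follow-up) from a societal perspective:
patient travel costs, time costs, production losses, and the emissions of the
car travel the video consultation avoids.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Arm(str, enum.Enum):
    """Randomized trial arm."""

    TELEMEDICINE = "telemedicine"
    CONTROL = "control"


class Indication(str, enum.Enum):
    KNEE = "knee"
    SHOULDER = "shoulder"


class AgeBand(str, enum.Enum):
    YOUNG = "18-40"
    MIDDLE = "41-60"
    OLDER = ">60"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class TransportMode(str, enum.Enum):
    CAR = "car"
    PUBLIC_TRANSPORT = "public_transport"


class PatientRecord(BaseModel):
    """One questionnaire row.

    Distances and travel times are stored ONE-WAY; round-trip doubling happens
    inside the cost and emission operations.  For the telemedicine arm the
    distance and travel time are hypothetical: what the patient would have
    faced had they travelled to the clinic.  Optional fields left as ``None``
    represent missing questionnaire items and are excluded per variable from
    aggregation, never by whole-record deletion.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    arm: Arm
    indication: Indication
    age_band: AgeBand
    sex: Sex
    employed: Optional[bool] = None
    one_way_distance_km: Optional[float] = Field(default=None, ge=0)
    travel_time_min: Optional[float] = Field(default=None, ge=0)
    waiting_time_min: Optional[float] = Field(default=None, ge=0)
    treatment_duration_min: Optional[float] = Field(default=None, ge=0)
    total_time_min: Optional[float] = Field(default=None, ge=0)
    absent_from_work: Optional[bool] = None
    transport_mode: TransportMode = TransportMode.CAR

    @model_validator(mode="after")
    def _absence_implies_employment(self) -> "PatientRecord":
        if self.absent_from_work is True and self.employed is not True:
            raise ValueError(
                "absent_from_work may only be true for a patient recorded as employed"
            )
        return self


class CostParameters(BaseModel):
    """Unit costs of the societal-perspective cost model.

    Defaults are the German base case: €0.30 per kilometer travelled
    (empirical standard cost recommendation), €16.00 per hour of unpaid work
    and leisure time, the 2021 average gross hourly wage of €29.48, and the
    average 6.96 working hours per day across full- and part-time employees.
    ``eur_to_usd`` is a display-only conversion rate.
    """

    model_config = ConfigDict(frozen=True)

    cost_per_km: float = Field(default=0.30, gt=0)
    time_value_per_hour: float = Field(default=16.00, gt=0)
    gross_hourly_wage: float = Field(default=29.48, gt=0)
    working_hours_per_day: float = Field(default=6.96, gt=0)
    eur_to_usd: float = Field(default=0.97, gt=0)


class VariableStats(BaseModel):
    """Summary statistics of one continuous questionnaire variable."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=0)
    mean: float
    sd: float = Field(ge=0)
    median: float
    q1: float
    q3: float


#: continuous PatientRecord fields summarised per arm, in reporting order
CONTINUOUS_VARIABLES = (
    "treatment_duration_min",
    "one_way_distance_km",
    "travel_time_min",
    "waiting_time_min",
    "total_time_min",
)

#: ArmAggregate attribute for each continuous PatientRecord field
AGGREGATE_FIELD_FOR = {
    "treatment_duration_min": "treatment_duration",
    "one_way_distance_km": "one_way_distance",
    "travel_time_min": "travel_time",
    "waiting_time_min": "waiting_time",
    "total_time_min": "total_time",
}


class ArmAggregate(BaseModel):
    """Group-level statistics of one arm, with per-variable denominators.

    ``n`` may differ between variables (missing questionnaire items are
    excluded per variable).  ``n_employed_known`` is the number of patients
    whose employment status is on record; ``n_employed`` of those are
    employed, and ``n_absent`` of the employed were absent from work for the
    appointment.
    """

    model_config = ConfigDict(frozen=True)

    arm: Arm
    n_records: int = Field(ge=1)
    treatment_duration: VariableStats
    one_way_distance: VariableStats
    travel_time: VariableStats
    waiting_time: VariableStats
    total_time: VariableStats
    n_employed_known: int = Field(ge=0)
    n_employed: int = Field(ge=0)
    n_absent: int = Field(ge=0)

    @model_validator(mode="after")
    def _counts_consistent(self) -> "ArmAggregate":
        for field in AGGREGATE_FIELD_FOR.values():
            stats: VariableStats = getattr(self, field)
            if stats.n > self.n_records:
                raise ValueError(f"{field}: n exceeds number of records")
        if self.n_employed_known > self.n_records:
            raise ValueError("n_employed_known exceeds number of records")
        if self.n_employed > self.n_employed_known:
            raise ValueError("n_employed exceeds n_employed_known")
        if self.n_absent > self.n_employed:
            raise ValueError("n_absent exceeds n_employed")
        return self

    def variable(self, record_field: str) -> VariableStats:
        """Return the stats block for a PatientRecord field name."""
        return getattr(self, AGGREGATE_FIELD_FOR[record_field])
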