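"""Reference permeability measurements and training data-set construction.

The packaged fixture holds the diffusion-cell permeability coefficients of
fentanyl and sufentanil across excised human skin: eleven donors (D01-D11)
measured with both compounds at vehicle pH 7.4 on heat-separated epidermis,
plus one donor (D12) measured with both compounds on dermatomed thigh skin
over nine vehicle pH levels (2.88-9.37).

Training data sets are combinations of twelve experiments arranged into five
design groups:

A: cross-over, 3 thigh + 3 abdomen donors, all pH 7.4 (three data sets);
B: as A, but one donor pair replaced by the D12 pH 9.37 pair (three data sets);
C: single site per data set (abdomen-only; thigh-only incl. the D12 pair);
D: single compound per data set, twelve donors incl. D12 at pH 9.37;
E: parallel design, six thigh donors on one compound (one at pH 9.37) and six
   abdomen donors on the other (two data sets).

Donor-to-data-set assignment within Groups A and B is a seeded constrained
randomization; Groups C, D and E are fully determined by the design counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentRecord",
    "TrainingDataSet",
    "load_reference_measurements",
    "reference_frame",
    "build_group_datasets",
    "dataset_from_frame",
    "THIGH_DONORS",
    "ABDOMEN_DONORS",
]

GROUPS = ("A", "B", "C", "D", "E")

#: Donor/site assignment of the pH 7.4 heat-separated experiments.
THIGH_DONORS = ("D01", "D02", "D03", "D05", "D07")
ABDOMEN_DONORS = ("D04", "D06", "D08", "D09", "D10", "D11")

_EXPECTED_ROWS = 40
_SPOT_VALUES = {  # experiment -> (P_mean in 1e-6 cm/s, vehicle_pH)
    "F01": (2.83, 7.40),
    "S05": (6.47, 7.40),
    "FpH1": (0.08, 2.88),
    "SpH9": (9.36, 9.37),
}


@dataclass(frozen=True)
class ExperimentRecord:
    """One steady-state permeability measurement (mean over replicates)."""

    experiment_name: str
    individual_id: str
    site: str
    preparation: str
    vehicle_pH: float
    compound: str
    n_replicates: int
    P_mean: float  # cm/s
    P_sd: float  # cm/s, replicate SD carried as metadata only

    def __post_init__(self) -> None:
        if not (self.P_mean > 0):
            raise ValueError(f"{self.experiment_name}: P_mean must be > 0")
        if self.P_sd < 0:
            raise ValueError(f"{self.experiment_name}: P_sd must be >= 0")


@dataclass(frozen=True)
class TrainingDataSet:
    """Twelve experiments forming one training data set of a design group."""

    group: str
    dataset_id: str
    records: tuple[ExperimentRecord, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if len(self.records) != 12:
            raise ValueError(
                f"{self.dataset_id}: a training data set holds exactly 12 "
                f"experiments, got {len(self.records)}"
            )

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(sorted({r.compound for r in self.records}))

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(sorted({r.site for r in self.records}))

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(sorted({r.individual_id for r in self.records}))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def _read_fixture() -> pd.DataFrame:
    with resources.files("skinperm.data").joinpath(
        "roy_flynn_permeability.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_reference_measurements() -> list[ExperimentRecord]:
    """Load the 40 packaged measurements (values in cm/s).

    Raises ValueError if the fixture fails its row-count/spot-value check.
    """
    df = _read_fixture()
    if len(df) != _EXPECTED_ROWS:
        raise ValueError(
            f"fixture checksum failure: expected {_EXPECTED_ROWS} rows, "
            f"got {len(df)}"
        )
    by_name = df.set_index("experiment")
    for name, (p6, ph) in _SPOT_VALUES.items():
        row = by_name.loc[name]
        if abs(row["P_mean_1e6_cm_s"] - p6) > 1e-12 or abs(row["vehicle_pH"] - ph) > 1e-12:
            raise ValueError(f"fixture checksum failure at experiment {name}")
    records = [
        ExperimentRecord(
            experiment_name=r.experiment,
            individual_id=r.individual_id,
            site=r.site,
            preparation=r.preparation,
            vehicle_pH=float(r.vehicle_pH),
            compound=r.compound,
            n_replicates=int(r.n_replicates),
            P_mean=float(r.P_mean_1e6_cm_s) * 1e-6,
            P_sd=float(r.P_sd_1e6_cm_s) * 1e-6,
        )
        for r in df.itertuples()
    ]
    return records


def reference_frame() -> pd.DataFrame:
    """Reference measurements as a DataFrame with P_mean/P_sd in cm/s."""
    return pd.DataFrame([r.__dict__ for r in load_reference_measurements()])


# ---------------------------------------------------------------------------
# Group construction
# ---------------------------------------------------------------------------


def _index_records() -> dict[tuple[str, str], ExperimentRecord]:
    """(individual_id or 'D12@pH', compound) -> record."""
    out: dict[tuple[str, str], ExperimentRecord] = {}
    for r in load_reference_measurements():
        key = r.individual_id if r.individual_id != "D12" else f"D12@{r.vehicle_pH:.2f}"
        out[(key, r.compound)] = r
    return out


def _pair(idx, donor_key: str) -> list[ExperimentRecord]:
    """Both-compound (cross-over) pair of records for one donor key."""
    return [idx[(donor_key, "fentanyl")], idx[(donor_key, "sufentanil")]]


def _distinct_choice(rng: np.random.Generator, pool, k: int, taken: set) -> tuple:
    """Sample k donors without replacement, preferring an unseen combination."""
    for _ in range(200):
        pick = tuple(sorted(rng.choice(list(pool), size=k, replace=False)))
        if pick not in taken:
            return pick
    return pick  # fall back to a repeat if the pool is exhausted


def build_group_datasets(group: str, assignment_seed: int = 0) -> list[TrainingDataSet]:
    """Construct the data sets of one design group from the reference tables.

    Every record is drawn from :func:`load_reference_measurements`; the same
    ``assignment_seed`` reproduces identical data sets.
    """
    group = group.upper()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(assignment_seed)
    idx = _index_records()
    d12_key = "D12@9.37"
    datasets: list[TrainingDataSet] = []

    if group in ("A", "B"):
        n_thigh_74 = 3 if group == "A" else 2
        if len(THIGH_DONORS) < n_thigh_74 or len(ABDOMEN_DONORS) < 3:
            raise ValueError("insufficient donors of a site for this design")
        taken: set = set()
        for i in range(3):
            thigh = _distinct_choice(rng, THIGH_DONORS, n_thigh_74, taken)
            abdomen = _distinct_choice(rng, ABDOMEN_DONORS, 3, taken)
            taken.update({thigh, abdomen})
            donors = list(thigh) + list(abdomen)
            if group == "B":
                donors.append(d12_key)  # the pH 9.37 cross-over pair
            records = list(
                itertools.chain.from_iterable(_pair(idx, d) for d in donors)
            )
            datasets.append(
                TrainingDataSet(group, f"{group}{i + 1}", tuple(records))
            )
    elif group == "C":
        c1 = list(
            itertools.chain.from_iterable(_pair(idx, d) for d in ABDOMEN_DONORS)
        )
        c2_donors = list(THIGH_DONORS) + [d12_key]
        c2 = list(itertools.chain.from_iterable(_pair(idx, d) for d in c2_donors))
        datasets = [
            TrainingDataSet("C", "C1", tuple(c1)),
            TrainingDataSet("C", "C2", tuple(c2)),
        ]
    elif group == "D":
        donors = list(THIGH_DONORS) + list(ABDOMEN_DONORS) + [d12_key]
        for i, compound in enumerate(("fentanyl", "sufentanil")):
            records = [idx[(d, compound)] for d in donors]
            datasets.append(TrainingDataSet("D", f"D{i + 1}", tuple(records)))
    else:  # group E
        thigh_keys = list(THIGH_DONORS) + [d12_key]
        for i, (cmp_thigh, cmp_abd) in enumerate(
            (("fentanyl", "sufentanil"), ("sufentanil", "fentanyl"))
        ):
            records = [idx[(d, cmp_thigh)] for d in thigh_keys]
            records += [idx[(d, cmp_abd)] for d in ABDOMEN_DONORS]
            datasets.append(TrainingDataSet("E", f"E{i + 1}", tuple(records)))

    for ds in datasets:
        validate_group_constraints(ds)
    return datasets


def dataset_from_frame(
    df: pd.DataFrame, group: str = "A", dataset_id: str = "custom"
) -> TrainingDataSet:
    """Build a TrainingDataSet from a tabular-text frame (P_mean in cm/s)."""
    records = tuple(
        ExperimentRecord(
            experiment_name=str(r.experiment_name),
            individual_id=str(r.individual_id),
            site=str(r.site),
            preparation=str(r.preparation),
            vehicle_pH=float(r.vehicle_pH),
            compound=str(r.compound),
            n_replicates=int(r.n_replicates),
            P_mean=float(r.P_mean),
            P_sd=float(r.P_sd),
        )
        for r in df.itertuples(index=False)
    )
    return TrainingDataSet(group, dataset_id, records)


def validate_group_constraints(ds: TrainingDataSet) -> None:
    """Check the design-group invariants of a training data set."""
    recs = ds.records
    by_donor: dict[str, set[str]] = {}
    for r in recs:
        by_donor.setdefault(r.individual_id, set()).add(r.compound)
    if ds.group in ("A", "B", "C"):
        for donor, cmps in by_donor.items():
            if cmps != {"fentanyl", "sufentanil"}:
                raise ValueError(
                    f"{ds.dataset_id}: cross-over design requires both "
                    f"compounds per donor; {donor} has {sorted(cmps)}"
                )
    if ds.group == "E":
        for donor, cmps in by_donor.items():
            if len(cmps) != 1:
                raise ValueError(
                    f"{ds.dataset_id}: parallel design requires one compound "
                    f"per donor; {donor} has {sorted(cmps)}"
                )
    if ds.group == "A":
        if any(r.vehicle_pH != 7.40 for r in recs):
            raise ValueError(f"{ds.dataset_id}: Group A uses pH 7.4 only")
    if ds.group == "B":
        high = {r.individual_id for r in recs if r.vehicle_pH > 9.0}
        low = {r.individual_id for r in recs if r.vehicle_pH == 7.40}
        if len(high) != 1 or len(low) != 5:
            raise ValueError(
                f"{ds.dataset_id}: Group B requires one pH 9.37 donor and "
                f"five pH 7.4 donors"
            )
    if ds.group == "C" and len({r.site for r in recs}) != 1:
        raise ValueError(f"{ds.dataset_id}: Group C uses a single site")
    if ds.group == "D" and len({r.compound for r in recs}) != 1:
        raise ValueError(f"{ds.dataset_id}: Group D uses a single compound")
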