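"""Data structures and I/O for one-dimensional mark-recapture movement studies.

A study reach of length ``L`` metres is divided into contiguous equal-length
sections; locations are continuous metres from the downstream end, and a fish
captured in section *s* is located at that section's midpoint.  Captures are
paired across sampling occasions into *movement replicates* — the unit of the
dispersal-observation likelihood: a start location ``X0``, an end location
``X1`` (observed only on recapture), a binary recapture state ``Y`` and the
elapsed time ``eta_days``.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: The four focal species of the motivating study, in descending abundance
#: of the two families (chubs, then sunfishes).
STUDY_SPECIES = (
    "creek_chub",
    "bluehead_chub",
    "green_sunfish",
    "redbreast_sunfish",
)

#: Minimum total length (mm) for an individual to carry a PIT tag.
TAGGING_THRESHOLD_MM = 60.0

CAPTURE_COLUMNS = ("tag_id", "species", "occasion", "section", "total_length_mm")
HABITAT_COLUMNS = ("occasion", "section", "area_m2", "hra_m2", "velocity_ms")
OCCASION_COLUMNS = ("occasion", "date")


class SchemaError(ValueError):
    """A table is missing required columns."""


class ValidationError(ValueError):
    """A row violates a data invariant (range, sign, uniqueness)."""


@dataclass(frozen=True)
class Occasion:
    """One sampling event of the whole reach."""

    index: int
    date: _dt.date
    julian_day: int
    interval_to_next: float | None = None  # days; None for the last occasion

    def __post_init__(self):
        if self.interval_to_next is not None and self.interval_to_next <= 0:
            raise ValidationError(
                f"occasion {self.index}: interval_to_next must be positive, "
                f"got {self.interval_to_next}"
            )


@dataclass(frozen=True)
class Section:
    """One spatial unit of the reach; index 1 is the most downstream."""

    index: int
    length_m: float = 10.0
    area_m2: float | None = None

    @property
    def midpoint_m(self) -> float:
        return section_midpoint(self.index, self.length_m)


@dataclass(frozen=True)
class CaptureRecord:
    """One fish in hand at one occasion and section."""

    tag_id: str
    species: str
    occasion: int
    section: int
    total_length_mm: float

    def __post_init__(self):
        if self.total_length_mm <= 0:
            raise ValidationError(
                f"tag {self.tag_id}: non-positive total length "
                f"{self.total_length_mm}"
            )


@dataclass
class MovementReplicate:
    """A capture paired with the following occasion.

    ``x1`` is present iff ``y == 1``; for unrecaptured replicates the end
    location is latent and handled by the likelihood (marginalized) or the
    sampler (augmented).  ``covariates`` holds the standardized predictor
    values looked up at the capture occasion and section.
    """

    replicate_id: str
    tag_id: str
    species: str
    occasion_t: int
    x0: float
    x1: float | None
    y: int
    eta_days: float
    section_t: int | None = None
    total_length_mm: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.y not in (0, 1):
            raise ValidationError(f"replicate {self.replicate_id}: y must be 0/1")
        if self.y == 1 and self.x1 is None:
            raise ValidationError(
                f"replicate {self.replicate_id}: recaptured but x1 missing"
            )
        if self.eta_days <= 0:
            raise ValidationError(
                f"replicate {self.replicate_id}: eta_days must be positive"
            )


def section_midpoint(
    section_index: int, section_length: float = 10.0, n_sections: int | None = None
) -> float:
    """Midpoint of a section in metres from the downstream end of the reach.

    Sections are half-open intervals ``[length*(s-1), length*s)`` anchored at
    the downstream end, so section 1 of a 10-m grid has midpoint 5.0.
    """
    if section_index < 1:
        raise ValidationError(f"section index {section_index} out of range (< 1)")
    if n_sections is not None and section_index > n_sections:
        raise ValidationError(
            f"section index {section_index} out of range (> {n_sections})"
        )
    return section_length * (section_index - 1) + section_length / 2.0


def read_occasions(path) -> list[Occasion]:
    """Read an occasions table (columns ``occasion``, ``date`` ISO 8601)."""
    df = pd.read_csv(path)
    missing = set(OCCASION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"occasions table missing columns {sorted(missing)}")
    df = df.sort_values("occasion").reset_index(drop=True)
    dates = [_dt.date.fromisoformat(str(d)) for d in df["date"]]
    if any(d1 <= d0 for d0, d1 in zip(dates, dates[1:])):
        raise ValidationError("occasion dates must be strictly increasing")
    occs = []
    for i, (idx, d) in enumerate(zip(df["occasion"], dates)):
        interval = (
            float((dates[i + 1] - d).days) if i + 1 < len(dates) else None
        )
        occs.append(
            Occasion(
                index=int(idx),
                date=d,
                julian_day=d.timetuple().tm_yday,
                interval_to_next=interval,
            )
        )
    return occs


def write_occasions(occasions: list[Occasion], path) -> None:
    pd.DataFrame(
        {"occasion": [o.index for o in occasions],
         "date": [o.date.isoformat() for o in occasions]}
    ).to_csv(path, index=False)


def read_habitat(path) -> pd.DataFrame:
    """Read a per-occasion, per-section habitat table.

    Extra survey columns (width, depth, substrate, ...) are accepted and
    carried through untouched; the model uses area, HRA and velocity.
    """
    df = pd.read_csv(path)
    missing = set(HABITAT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"habitat table missing columns {sorted(missing)}")
    if (df["area_m2"] <= 0).any():
        raise ValidationError("habitat table contains non-positive section areas")
    if (df[["hra_m2", "velocity_ms"]] < 0).any().any():
        raise ValidationError("habitat table contains negative HRA or velocity")
    return df


def read_captures(
    path,
    species_set: list[str] | tuple[str, ...] = STUDY_SPECIES,
    n_occasions: int | None = None,
    n_sections: int | None = None,
) -> list[CaptureRecord]:
    """Read and validate a capture table, dropping non-target species.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for out-of-range occasions/sections,
    non-positive lengths, or duplicate (tag, occasion) rows.
    """
    df = pd.read_csv(path)
    missing = set(CAPTURE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"capture table missing columns {sorted(missing)}")
    n_raw = len(df)
    keep = df["species"].isin(species_set)
    dropped = int(n_raw - keep.sum())
    if dropped:
        logger.info("read_captures: dropped %d rows of non-target species", dropped)
    df = df[keep]
    records = []
    for row in df.itertuples(index=True):
        if row.total_length_mm <= 0:
            raise ValidationError(
                f"row {row.Index}: non-positive length {row.total_length_mm}"
            )
        occ, sec = int(row.occasion), int(row.section)
        if occ < 1 or (n_occasions is not None and occ > n_occasions):
            raise ValidationError(f"row {row.Index}: occasion {occ} out of range")
        if sec < 1 or (n_sections is not None and sec > n_sections):
            raise ValidationError(f"row {row.Index}: section {sec} out of range")
        records.append(
            CaptureRecord(
                tag_id=str(row.tag_id),
                species=str(row.species),
                occasion=occ,
                section=sec,
                total_length_mm=float(row.total_length_mm),
            )
        )
    seen = set()
    for rec in records:
        key = (rec.tag_id, rec.occasion)
        if key in seen:
            raise ValidationError(
                f"tag {rec.tag_id} captured twice at occasion {rec.occasion}"
            )
        seen.add(key)
    return records


def write_captures(records: list[CaptureRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records])[
        list(CAPTURE_COLUMNS)
    ].to_csv(path, index=False)


def captures_to_frame(records: list[CaptureRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def build_replicates(
    records: list[CaptureRecord],
    occasions: list[Occasion],
    pairing: str = "strict_consecutive",
    section_length: float = 10.0,
) -> list[MovementReplicate]:
    """Pair captures across occasions into movement replicates.

    ``strict_consecutive`` (default): every capture at occasion ``t < T``
    yields one replicate; ``y = 1`` with observed ``x1`` iff the individual
    was captured at ``t + 1``, else ``y = 0`` with ``x1`` latent.  An
    individual recaptured after skipping an occasion re-enters as a fresh
    replicate; the intermediate ``y = 0`` replicate is retained.

    ``next_capture``: each capture is paired with the individual's next
    capture at *any* later occasion (``eta_days`` is the actual elapsed
    time); captures never seen again yield a ``y = 0`` replicate over the
    next inter-occasion interval.
    """
    if pairing not in ("strict_consecutive", "next_capture"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    occ_by_index = {o.index: o for o in occasions}
    T = max(occ_by_index)

    by_tag: dict[str, dict[int, CaptureRecord]] = {}
    for rec in records:
        caps = by_tag.setdefault(rec.tag_id, {})
        if rec.occasion in caps:
            raise ValidationError(
                f"tag {rec.tag_id} captured twice at occasion {rec.occasion}"
            )
        caps[rec.occasion] = rec

    def elapsed(t0: int, t1: int) -> float:
        return float(
            sum(occ_by_index[t].interval_to_next for t in range(t0, t1))
        )

    replicates = []
    for tag_id in sorted(by_tag):
        caps = by_tag[tag_id]
        for t in sorted(caps):
            if t >= T:
                continue
            rec = caps[t]
            x0 = section_midpoint(rec.section, section_length)
            if pairing == "strict_consecutive":
                nxt = caps.get(t + 1)
                eta = occ_by_index[t].interval_to_next
                t_end = t + 1
            else:
                later = sorted(u for u in caps if u > t)
                nxt = caps[later[0]] if later else None
                t_end = later[0] if later else t + 1
                eta = elapsed(t, t_end)
            replicates.append(
                MovementReplicate(
                    replicate_id=f"{tag_id}:{t}",
                    tag_id=tag_id,
                    species=rec.species,
                    occasion_t=t,
                    x0=x0,
                    x1=(
                        section_midpoint(nxt.section, section_length)
                        if nxt is not None
                        else None
                    ),
                    y=int(nxt is not None),
                    eta_days=float(eta),
                    section_t=rec.section,
                    total_length_mm=rec.total_length_mm,
                )
            )
    return replicates


def recapture_tallies(replicates: list[MovementReplicate]) -> dict[str, int]:
    """Recapture accounting under both conventions.

    ``events`` counts individual-by-interval recapture events (``y = 1``
    replicates); ``individuals`` counts distinct tags with at least one
    such event.
    """
    recaptured = [r for r in replicates if r.y == 1]
    return {
        "events": len(recaptured),
        "individuals": len({r.tag_id for r in recaptured}),
    }
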