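"""Trial-level summary data: containers, file I/O and count arithmetic.

A trial is summarised by per-arm sample sizes, per-arm biomarker responder
counts and (for historical trials) per-arm clinical-endpoint responder
counts.  The package ships a small worked-example table of five historical
vaccine trials (infection = biomarker, disease = endpoint) plus helper
arithmetic for the treatment-share proportion ``phi`` and vaccine efficacy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "TrialSummary",
    "SchemaError",
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "phi_hat",
    "vaccine_efficacy",
    "load_example_trials",
    "EXAMPLE_NEW_TRIAL",
]

_COLUMNS = ("trial_id", "n_t", "n_c", "b_t", "b_c", "x_t", "x_c")


class SchemaError(ValueError):
    """A trial table is missing required columns."""


class TrialValidationError(ValueError):
    """A trial row violates count invariants."""


@dataclass(frozen=True)
class TrialSummary:
    """Per-arm summary counts for one randomized trial.

    ``x_t``/``x_c`` are ``None`` for a new trial whose clinical endpoint has
    not yet been observed.
    """

    trial_id: str
    n_t: int
    n_c: int
    b_t: int
    b_c: int
    x_t: Optional[int] = None
    x_c: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("n_t", "n_c", "b_t", "b_c"):
            _check_count(self.trial_id, name, getattr(self, name))
        for name in ("x_t", "x_c"):
            if getattr(self, name) is not None:
                _check_count(self.trial_id, name, getattr(self, name))
        if (self.x_t is None) != (self.x_c is None):
            raise TrialValidationError(
                f"trial {self.trial_id!r}: endpoint counts must be given for "
                "both arms or neither"
            )
        if self.n_t <= 0 or self.n_c <= 0:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: arm sizes must be positive"
            )
        if self.b_t > self.n_t or self.b_c > self.n_c:
            raise TrialValidationError(
                f"trial {self.trial_id!r}: biomarker count exceeds arm size"
            )
        if self.x_t is not None:
            if self.x_t > self.n_t or self.x_c > self.n_c:
                raise TrialValidationError(
                    f"trial {self.trial_id!r}: endpoint count exceeds arm size"
                )

    @property
    def b(self) -> int:
        """Total biomarker responders across both arms."""
        return self.b_t + self.b_c

    @property
    def x(self) -> Optional[int]:
        """Total endpoint responders across both arms (None for new trials)."""
        if self.x_t is None:
            return None
        return self.x_t + self.x_c

    @property
    def has_endpoint(self) -> bool:
        return self.x_t is not None


def _check_count(trial_id: str, name: str, value) -> None:
    if isinstance(value, bool) or not isinstance(value, int):
        raise TrialValidationError(
            f"trial {trial_id!r}: {name}={value!r} is not an integer"
        )
    if value < 0:
        raise TrialValidationError(
            f"trial {trial_id!r}: {name}={value} is negative"
        )


def _parse_int(trial_id: str, name: str, raw: str) -> Optional[int]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = int(raw)
    except ValueError:
        raise TrialValidationError(
            f"trial {trial_id!r}: {name}={raw!r} is not an integer"
        ) from None
    return value


def read_trials(path, fmt: Optional[str] = None) -> list[TrialSummary]:
    """Read a trial summary table from a CSV or TSV file.

    The header must contain the columns ``trial_id,n_t,n_c,b_t,b_c,x_t,x_c``
    (endpoint cells may be empty for new trials).  Rows violating the count
    invariants raise :class:`TrialValidationError` with the offending
    ``trial_id``; missing columns raise :class:`SchemaError`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    delimiter = "\t" if fmt == "tsv" else ","
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        trials = []
        for idx, row in enumerate(reader, start=2):
            trial_id = (row["trial_id"] or "").strip() or f"row{idx}"
            try:
                trials.append(
                    TrialSummary(
                        trial_id=trial_id,
                        n_t=_parse_int(trial_id, "n_t", row["n_t"]),
                        n_c=_parse_int(trial_id, "n_c", row["n_c"]),
                        b_t=_parse_int(trial_id, "b_t", row["b_t"]),
                        b_c=_parse_int(trial_id, "b_c", row["b_c"]),
                        x_t=_parse_int(trial_id, "x_t", row["x_t"]),
                        x_c=_parse_int(trial_id, "x_c", row["x_c"]),
                    )
                )
            except TrialValidationError as err:
                raise TrialValidationError(f"line {idx}: {err}") from None
    return trials


def write_trials(trials: Iterable[TrialSummary], path, fmt: Optional[str] = None) -> None:
    """Write trials to CSV/TSV with the canonical column layout."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    delimiter = "\t" if fmt == "tsv" else ","
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for t in trials:
            writer.writerow(
                [
                    t.trial_id,
                    t.n_t,
                    t.n_c,
                    t.b_t,
                    t.b_c,
                    "" if t.x_t is None else t.x_t,
                    "" if t.x_c is None else t.x_c,
                ]
            )


def phi_hat(count_t: int, count_c: int, ratio: float = 1.0) -> float:
    """Estimate the treatment-arm share of responders.

    ``count_t / (count_t + ratio * count_c)`` where ``ratio`` is the
    treatment-to-control sample-size ratio (1 for the balanced designs used
    throughout).  The same formula estimates both the biomarker share and
    the endpoint share.  Under 1:1 allocation ``phi / (1 - phi)`` is the
    between-arm rate ratio.
    """
    if ratio <= 0:
        raise ValueError("sample-size ratio must be positive")
    if count_t < 0 or count_c < 0:
        raise ValueError("counts must be non-negative")
    if count_t + count_c == 0:
        raise ZeroDivisionError(
            "proportion undefined: no responders in either arm"
        )
    return count_t / (count_t + ratio * count_c)


def vaccine_efficacy(rr: float) -> float:
    """Vaccine efficacy ``1 - RR`` for a non-negative rate ratio."""
    if rr < 0:
        raise ValueError("rate ratio must be non-negative")
    return 1.0 - rr


def load_example_trials() -> list[TrialSummary]:
    """Load the packaged five-trial historical vaccine example."""
    ref = resources.files("biobridge.data").joinpath("vaccine_example.csv")
    with resources.as_file(ref) as path:
        return read_trials(path)


#: the new regional trial of the worked example: 3606 subjects split 1:1,
#: 36 infection cases (7 vaccine / 29 placebo), disease not yet observed
EXAMPLE_NEW_TRIAL = TrialSummary(
    trial_id="new", n_t=1803, n_c=1803, b_t=7, b_c=29
)
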