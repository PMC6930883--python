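"""Readers and writers for SNP-array panels, class labels, and rule lists.

The on-disk formats are deliberately plain text:

* wide TSV signal matrices (rows = samples, columns = marker ids),
* two-column TSV label files,
* GenomeStudio-final-report-style long TSV (``SNP Name`` / ``Sample ID`` /
  ``Log R Ratio`` / ``B Allele Freq``),
* one-rule-per-line decision-list files.

A published 17-rule decision list for MACROD2 deletion status learned from
LRR signals ships with the package and is available through
:func:`load_published_macrod2_rules`.
"""

from __future__ import annotations

import enum
import io
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalKind",
    "SNPMarker",
    "SignalMatrix",
    "LabeledDataset",
    "Condition",
    "Rule",
    "RuleList",
    "read_signal_matrix",
    "write_signal_matrix",
    "read_labels",
    "write_labels",
    "read_marker_map",
    "write_marker_map",
    "read_final_report",
    "parse_rule_text",
    "serialize_rule_list",
    "load_published_macrod2_rules",
]


class SignalKind(str, enum.Enum):
    """Which array-derived signal a matrix holds."""

    LRR = "LRR"  # log R ratio: ~0 diploid, depressed under deletion
    BAF = "BAF"  # B allele frequency: in [0, 1], clusters at 0/0.5/1

    @classmethod
    def coerce(cls, value: "SignalKind | str") -> "SignalKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(f"unknown signal kind {value!r}; expected LRR or BAF") from None


@dataclass(frozen=True)
class SNPMarker:
    """A SNP locus on the array panel."""

    marker_id: str
    chromosome: str = "NA"
    position: int = 1

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.marker_id}: position must be >= 1 (1-based bp)")


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class SignalMatrix:
    """A samples x markers panel of one real-valued array signal."""

    sample_ids: list[str]
    markers: list[SNPMarker]
    values: np.ndarray
    signal_kind: SignalKind

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.signal_kind = SignalKind.coerce(self.signal_kind)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()
        self._col_index = {m.marker_id: j for j, m in enumerate(self.markers)}

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("signal values must be a 2-D samples x markers array")
        n, m = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} value rows")
        if m != len(self.markers):
            raise ValueError(f"{len(self.markers)} markers for {m} value columns")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise ValueError(f"duplicate sample ids: {', '.join(dups)}")
        dups = _find_duplicates([mk.marker_id for mk in self.markers])
        if dups:
            raise ValueError(f"duplicate marker ids: {', '.join(dups)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"marker {self.markers[bad[1]].marker_id!r}"
            )
        if self.signal_kind is SignalKind.BAF and self.values.size:
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValueError("BAF values must lie in [0, 1]")

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def column(self, marker_id: str) -> np.ndarray:
        try:
            return self.values[:, self._col_index[marker_id]]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not present in panel") from None

    def column_indices(self, marker_ids: Sequence[str]) -> np.ndarray:
        missing = [m for m in marker_ids if m not in self._col_index]
        if missing:
            raise KeyError(f"markers not present in panel: {', '.join(missing)}")
        return np.array([self._col_index[m] for m in marker_ids], dtype=int)

    def subset(self, marker_ids: Sequence[str]) -> "SignalMatrix":
        idx = self.column_indices(marker_ids)
        return SignalMatrix(
            sample_ids=list(self.sample_ids),
            markers=[self.markers[j] for j in idx],
            values=self.values[:, idx].copy(),
            signal_kind=self.signal_kind,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.marker_ids)


@dataclass
class LabeledDataset:
    """A signal panel with one categorical class label per sample."""

    signal: SignalMatrix
    labels: list[str]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.class_names = tuple(str(c) for c in self.class_names)
        if len(self.labels) != self.signal.n_samples:
            raise ValueError(
                f"{len(self.labels)} labels for {self.signal.n_samples} samples"
            )
        unknown = sorted(set(self.labels) - set(self.class_names))
        if unknown:
            raise ValueError(f"labels outside class_names: {', '.join(unknown)}")
        if len(self.class_names) != len(set(self.class_names)):
            raise ValueError("duplicate class names")

    @property
    def n_samples(self) -> int:
        return self.signal.n_samples

    @property
    def n_features(self) -> int:
        return self.signal.n_markers

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def class_sizes(self) -> dict[str, int]:
        y = self.y
        return {c: int(np.sum(y == c)) for c in self.class_names}

    def subset_features(self, marker_ids: Sequence[str]) -> "LabeledDataset":
        return LabeledDataset(self.signal.subset(marker_ids), list(self.labels), self.class_names)


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

_OPS = ("<=", ">=")


@dataclass(frozen=True)
class Condition:
    """One inclusive threshold comparison on a marker's signal value."""

    marker_id: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}; expected one of {_OPS}")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value >= self.threshold

    def __str__(self) -> str:
        return f"{self.marker_id} {self.op} {self.threshold!r}"


def _check_pct(name: str, value: float | None) -> None:
    if value is not None and not (0.0 <= value <= 100.0 or math.isnan(value)):
        raise ValueError(f"{name} must lie in [0, 100], got {value}")


@dataclass(frozen=True)
class Rule:
    """An IF-THEN rule: a conjunction of conditions implying a class."""

    conditions: tuple[Condition, ...]
    consequent: str
    support_pct: float | None = None
    accuracy_pct: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        _check_pct("support_pct", self.support_pct)
        _check_pct("accuracy_pct", self.accuracy_pct)

    @property
    def is_default(self) -> bool:
        return len(self.conditions) == 0

    def matches(self, lookup: Mapping[str, float]) -> bool:
        return all(c.holds(lookup[c.marker_id]) for c in self.conditions)


@dataclass(frozen=True)
class RuleList:
    """An ordered decision list; the last rule is the conditionless default."""

    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        if not self.rules:
            raise ValueError("a rule list needs at least the default rule")
        if not self.rules[-1].is_default:
            raise ValueError("last rule must be the conditionless default")
        for i, r in enumerate(self.rules[:-1]):
            if r.is_default:
                raise ValueError(f"rule {i + 1} has no conditions but is not last")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def conditioned(self) -> tuple[Rule, ...]:
        return self.rules[:-1]

    @property
    def default_class(self) -> str:
        return self.rules[-1].consequent

    @property
    def marker_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.conditioned:
            for c in r.conditions:
                seen.setdefault(c.marker_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# Matrix / label / marker-map TSV
# ---------------------------------------------------------------------------


def _read_table_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [ln for ln in text.splitlines() if ln and not ln.startswith("#")]


def write_signal_matrix(
    matrix: SignalMatrix,
    path: str | Path,
    *,
    float_fmt: str = "%.6f",
    header_comment: str | None = None,
) -> None:
    """Write a wide TSV: header ``sample_id`` + marker ids, one row per sample."""
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write("sample_id\t" + "\t".join(matrix.marker_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(float_fmt % v for v in row) + "\n")


def read_signal_matrix(
    path: str | Path,
    signal_kind: SignalKind | str,
    *,
    markers: Sequence[SNPMarker] | None = None,
) -> SignalMatrix:
    """Read a wide TSV signal matrix.

    ``markers`` may supply chromosome/position metadata (e.g. from
    :func:`read_marker_map`); ids must then cover the file's columns.
    """
    lines = _read_table_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: header must name at least one marker column")
    marker_ids = header[1:]
    dups = _find_duplicates(marker_ids)
    if dups:
        raise ValueError(f"{path}: repeated marker column(s): {', '.join(dups)}")
    if len(lines) == 1:
        raise ValueError(f"{path}: no samples")
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"{path}: line {i}: expected {len(header)} columns, got {len(cells)}")
        sample_ids.append(cells[0])
        row = []
        for j, cell in enumerate(cells[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at sample {cells[0]!r}, "
                    f"marker {marker_ids[j]!r}"
                ) from None
        rows.append(row)
    if markers is not None:
        by_id = {m.marker_id: m for m in markers}
        missing = [m for m in marker_ids if m not in by_id]
        if missing:
            raise ValueError(f"marker map lacks: {', '.join(missing[:5])}")
        marker_objs = [by_id[m] for m in marker_ids]
    else:
        marker_objs = [SNPMarker(m) for m in marker_ids]
    return SignalMatrix(sample_ids, marker_objs, np.array(rows, dtype=float), signal_kind)


def write_labels(
    sample_ids: Sequence[str],
    labels: Sequence[str],
    path: str | Path,
    *,
    header_comment: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(sample_ids, labels):
            fh.write(f"{sid}\t{lab}\n")


def read_labels(path: str | Path) -> tuple[list[str], list[str]]:
    lines = _read_table_lines(path)
    if len(lines) < 2:
        raise ValueError(f"{path}: no samples")
    sample_ids, labels = [], []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != 2:
            raise ValueError(f"{path}: expected 2 columns, got {len(cells)}")
        sample_ids.append(cells[0])
        labels.append(cells[1])
    return sample_ids, labels


def write_marker_map(
    markers: Sequence[SNPMarker], path: str | Path, *, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write("marker_id\tchromosome\tposition\n")
        for m in markers:
            fh.write(f"{m.marker_id}\t{m.chromosome}\t{m.position}\n")


def read_marker_map(path: str | Path) -> list[SNPMarker]:
    lines = _read_table_lines(path)
    out = []
    for ln in lines[1:]:
        mid, chrom, pos = ln.split("\t")
        out.append(SNPMarker(mid, chrom, int(pos)))
    return out


# ---------------------------------------------------------------------------
# GenomeStudio-style final report (long format)
# ---------------------------------------------------------------------------

_REPORT_COLS = ("SNP Name", "Sample ID", "Log R Ratio", "B Allele Freq")


def read_final_report(path: str | Path) -> tuple[SignalMatrix, SignalMatrix]:
    """Parse a GenomeStudio-final-report-style long TSV into (LRR, BAF) matrices.

    A metadata block before a ``[Data]`` line is tolerated. Every
    (sample, marker) pair must appear exactly once; optional ``Chr`` and
    ``Position`` columns populate the marker map.
    """
    raw = Path(path).read_text().splitlines()
    start = 0
    for i, ln in enumerate(raw):
        if ln.strip() == "[Data]":
            start = i + 1
            break
    df = pd.read_csv(io.StringIO("\n".join(raw[start:])), sep="\t")
    missing = [c for c in _REPORT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["SNP Name", "Sample ID"], keep=False)
    if dup.any():
        first = df.loc[dup, ["Sample ID", "SNP Name"]].iloc[0]
        raise ValueError(
            f"{path}: (sample, marker) pair appears twice: "
            f"({first['Sample ID']!r}, {first['SNP Name']!r})"
        )
    samples = list(dict.fromkeys(df["Sample ID"].astype(str)))
    snps = list(dict.fromkeys(df["SNP Name"].astype(str)))
    expected = len(samples) * len(snps)
    if len(df) != expected:
        have = set(zip(df["Sample ID"].astype(str), df["SNP Name"].astype(str)))
        gaps = [
            (s, m) for s in samples for m in snps if (s, m) not in have
        ]
        raise ValueError(f"{path}: missing (sample, marker) rows: {gaps[:5]}")
    if "Chr" in df.columns and "Position" in df.columns:
        meta = df.drop_duplicates("SNP Name").set_index("SNP Name")
        markers = [
            SNPMarker(m, str(meta.loc[m, "Chr"]), int(meta.loc[m, "Position"])) for m in snps
        ]
    else:
        markers = [SNPMarker(m) for m in snps]
    lrr = df.pivot(index="Sample ID", columns="SNP Name", values="Log R Ratio")
    baf = df.pivot(index="Sample ID", columns="SNP Name", values="B Allele Freq")
    lrr = lrr.reindex(index=samples, columns=snps)
    baf = baf.reindex(index=samples, columns=snps)
    return (
        SignalMatrix(samples, markers, lrr.to_numpy(float), SignalKind.LRR),
        SignalMatrix(samples, markers, baf.to_numpy(float), SignalKind.BAF),
    )


# ---------------------------------------------------------------------------
# Rule text
# ---------------------------------------------------------------------------

# typeset minus / dash variants normalized to ASCII hyphen-minus
_DASHES = dict.fromkeys(map(ord, "−–—‑"), "-")

_ANNOT_RE = re.compile(r"\[\s*support=([^\s\]]+)\s+accuracy=([^\s\]]+)\s*\]\s*$")
_COND_RE = re.compile(r"^(\S+)\s*(<=|>=)\s*(\S+)$")


def _parse_rule_line(line: str, lineno: int) -> Rule:
    line = line.translate(_DASHES).strip()
    support = accuracy = None
    m = _ANNOT_RE.search(line)
    if m:
        support, accuracy = float(m.group(1)), float(m.group(2))
        line = line[: m.start()].strip()
    if line.upper().startswith("OTHERS"):
        body = line[len("OTHERS"):].strip()
        if not body.upper().startswith("THEN"):
            raise ValueError(f"line {lineno}: malformed default rule")
        cls = _parse_consequent(body, lineno)
        return Rule((), cls, support, accuracy)
    if not line.upper().startswith("IF "):
        raise ValueError(f"line {lineno}: rule must start with IF or OTHERS")
    try:
        cond_part, then_part = re.split(r"\s+THEN\s+", line[3:], maxsplit=1, flags=re.I)
    except ValueError:
        raise ValueError(f"line {lineno}: missing THEN clause") from None
    conditions = []
    for chunk in re.split(r"\s+AND\s+", cond_part, flags=re.I):
        cm = _COND_RE.match(chunk.strip())
        if not cm:
            op = re.search(r"[<>=!]+", chunk)
            raise ValueError(
                f"line {lineno}: cannot parse condition {chunk.strip()!r}"
                + (f" (unknown operator {op.group(0)!r})" if op and op.group(0) not in _OPS else "")
            )
        try:
            thr = float(cm.group(3))
        except ValueError:
            raise ValueError(
                f"line {lineno}: threshold {cm.group(3)!r} is not numeric"
            ) from None
        conditions.append(Condition(cm.group(1), cm.group(2), thr))
    cls = _parse_consequent("THEN " + then_part, lineno)
    return Rule(tuple(conditions), cls, support, accuracy)


def _parse_consequent(then_clause: str, lineno: int) -> str:
    m = re.match(r"THEN\s+class\s*=\s*(.+)$", then_clause.strip(), flags=re.I)
    if not m:
        raise ValueError(f"line {lineno}: expected 'THEN class = <name>'")
    return m.group(1).strip().strip('"')


def parse_rule_text(text: str) -> RuleList:
    """Parse one-rule-per-line decision-list text into a :class:`RuleList`."""
    rules = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rules.append(_parse_rule_line(line, lineno))
    if not rules or not rules[-1].is_default:
        raise ValueError("rule text must end with a default rule ('OTHERS THEN class = ...')")
    return RuleList(tuple(rules))


def serialize_rule_list(rules: RuleList) -> str:
    """Render a rule list as text; ``parse_rule_text`` inverts this exactly."""
    lines = []
    for r in rules:
        if r.is_default:
            body = f"OTHERS THEN class = {r.consequent}"
        else:
            conds = " AND ".join(f"{c.marker_id} {c.op} {c.threshold!r}" for c in r.conditions)
            body = f"IF {conds} THEN class = {r.consequent}"
        if r.support_pct is not None and r.accuracy_pct is not None:
            body += f" [support={r.support_pct:.2f} accuracy={r.accuracy_pct:.2f}]"
        lines.append(body)
    return "\n".join(lines) + "\n"


def load_published_macrod2_rules() -> RuleList:
    """The published 17-rule MACROD2-status decision list learned from LRR.

    Eight rules call homozygous deletion, eight call wild-type, and the
    default assigns heterozygous deletion; each carries the reported
    support and accuracy percentages.
    """
    text = resources.files("cnvrules").joinpath("fixtures/macrod2_lrr_rules.txt").read_text()
    return parse_rule_text(text)
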