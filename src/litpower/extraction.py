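"""Two-phase text mining of full t-test records from article plain text.

Phase one (:func:`harvest_candidate_lines`) scans each physical line of the
article body for ``t(`` / ``t`` anchors, reads a 65-character window with
all spaces removed and everything lowercased, and keeps windows that look
like they could hold a complete report: they must contain one of ``=``,
``<``, ``>`` and additionally a ``p=``, ``p<`` or ``p>`` token. Restricting
to full records with a p clause keeps the false-alarm rate at zero at the
cost of missing stand-alone t-values (``t < 1`` and the like).

Phase two (:func:`parse_t_record`) applies a start-anchored regular
expression for the ``t(df) = x.xx, p = y.yy[, d = z.zz]`` template family
and returns a :class:`~litpower.records_io.StatRecord`, or nothing — never
a partial record.

:func:`clean_records` applies the post-extraction hygiene rules: adjacent
duplicates, impossible values (negative p, non-positive df) and absurdly
large degrees of freedom (> 10,000) are dropped, each with a
machine-readable reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records_io import StatRecord

#: window length, counted after space removal
WINDOW = 65

#: df above which a record is treated as an outlier and dropped
DF_OUTLIER = 10_000

_SPACE_RX = re.compile(r"[ \t]+")
_P_TOKENS = ("p=", "p<", "p>")

# number: 2.45, .022, 0.022, 12 — no thousands separators
_NUM = r"(?:\d+\.\d+|\.\d+|\d+)"
# t clause with a single integer df (an F-style "t(2,45)" must not match),
# then a p clause, then an optional d clause; clauses separated by , ; : or
# nothing (spaces are already gone)
_RECORD_RX = re.compile(
    rf"^t\((\d+)\)=(-?{_NUM})"
    rf"[,;:]*p([=<>])({_NUM})"
    rf"(?:[,;:]*d=(-?{_NUM}))?"
)


@dataclass(frozen=True)
class CandidateLine:
    """A lowercased, space-free 65-character window at a ``t`` anchor."""

    text: str
    offset: int

    def __post_init__(self):
        if " " in self.text:
            raise ValueError("candidate line must not contain spaces")
        if self.text != self.text.lower():
            raise ValueError("candidate line must be lowercase")


def _normalise(line: str) -> str:
    """Space removal, lowercasing, unicode-minus folding."""
    return _SPACE_RX.sub("", line).lower().replace("−", "-").replace("–", "-")


def harvest_candidate_lines(body: str) -> list[CandidateLine]:
    """Locate candidate t-test report windows in an article body.

    Anchors are taken per physical line (a record broken across a line
    break is therefore lost, mirroring how PDF text extraction behaves).
    ``t(`` anchors are always considered; a bare ``t`` anchor only when an
    ``=`` or ``(`` follows within the window. A window is retained only if
    it contains one of ``=<>`` and one of ``p=``, ``p<``, ``p>``.
    """
    out: list[CandidateLine] = []
    offset = 0
    for raw_line in body.splitlines():
        line = _normalise(raw_line)
        for i, ch in enumerate(line):
            if ch != "t":
                continue
            window = line[i : i + WINDOW]
            if not window.startswith("t("):
                if "=" not in window and "(" not in window:
                    continue
            if not any(c in window for c in "=<>"):
                continue
            if not any(tok in window for tok in _P_TOKENS):
                continue
            out.append(CandidateLine(text=window, offset=offset + i))
        offset += len(line) + 1
    return out


def parse_t_record(line: CandidateLine | str) -> StatRecord | None:
    """Parse one candidate window into a record, or return ``None``.

    The template must match at the very start of the window, so a stray
    leading ``t`` (e.g. from ``effectt(23)=...``) never yields a record:
    the anchor sitting exactly on ``t(`` does instead.
    """
    text = line.text if isinstance(line, CandidateLine) else _normalise(line)
    m = _RECORD_RX.match(text)
    if m is None:
        return None
    df = int(m.group(1))
    t_value = float(m.group(2))
    p_cmp = m.group(3)
    p_value = float(m.group(4))
    if not 0.0 < p_value <= 1.0:
        # a "p-value" outside (0, 1] means we matched something that is
        # not a real probability report; reject the whole window
        return None
    d_value = float(m.group(5)) if m.group(5) is not None else None
    return StatRecord(
        df=df,
        t_value=t_value,
        p_cmp=p_cmp,
        p_reported=p_value,
        d_reported=d_value,
        line_source=text,
    )


def extract_records(body: str, paper_id: str | None = None) -> list[StatRecord]:
    """Run both parsing phases over one article body."""
    records = []
    for cand in harvest_candidate_lines(body):
        rec = parse_t_record(cand)
        if rec is not None:
            if paper_id is not None:
                rec = StatRecord(
                    df=rec.df,
                    t_value=rec.t_value,
                    paper_id=paper_id,
                    journal_id=rec.journal_id,
                    p_cmp=rec.p_cmp,
                    p_reported=rec.p_reported,
                    d_reported=rec.d_reported,
                    line_source=rec.line_source,
                )
            records.append(rec)
    return records


#: drop reasons emitted by clean_records
DROP_DUPLICATE = "duplicate"
DROP_DF_OUTLIER = "df_outlier"
DROP_NEGATIVE_P = "negative_p"
DROP_NONPOSITIVE_DF = "nonpositive_df"


def clean_records(
    records: Sequence[StatRecord],
) -> tuple[list[StatRecord], list[tuple[StatRecord, str]]]:
    """Apply post-extraction cleaning, in document order.

    Drops, with reasons:

    - ``duplicate`` — statistical fields identical to the immediately
      preceding kept record (the same report picked up twice);
    - ``nonpositive_df`` — degrees of freedom below 1;
    - ``negative_p`` — a reported p below 0;
    - ``df_outlier`` — degrees of freedom above 10,000.

    Idempotent: cleaning a cleaned list changes nothing.
    """
    kept: list[StatRecord] = []
    dropped: list[tuple[StatRecord, str]] = []
    prev_key = None
    for rec in records:
        if rec.df < 1:
            dropped.append((rec, DROP_NONPOSITIVE_DF))
            continue
        if rec.p_reported is not None and rec.p_reported < 0:
            dropped.append((rec, DROP_NEGATIVE_P))
            continue
        if rec.df > DF_OUTLIER:
            dropped.append((rec, DROP_DF_OUTLIER))
            continue
        key = rec.stat_key()
        if prev_key is not None and key == prev_key:
            dropped.append((rec, DROP_DUPLICATE))
            continue
        kept.append(rec)
        prev_key = key
    return kept, dropped
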