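"""Serialization of generated lists.

Two tab-separated outputs: the *list file* (one row per selected item,
with its list, presentation phases, item type and cosine distance to the
list centroid) and the *close-space report* (every close-space item of
every list, selected or not, plus the unrelated lures, sorted by distance
— the raw material for custom re-sampling designs).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .generation import DRMList
from .space import VectorSpace

__all__ = [
    "OutputRecord",
    "write_list_output",
    "read_list_output",
    "write_close_space_report",
]

LIST_HEADER = ("item", "list", "encoding", "recognition", "type", "distance")

TYPE_STUDIED = "Studied"
TYPE_CRITICAL = "Critical Lure"
TYPE_UNRELATED = "Unrelated Lure"


@dataclass(frozen=True)
class OutputRecord:
    """One row of the list file."""

    item: str
    list_id: int
    in_encoding: bool
    in_recognition: bool
    item_type: str
    distance: float


def records_for(lists: list[DRMList], space: VectorSpace) -> list[OutputRecord]:
    """Flatten lists into output rows, ascending distance within each list."""
    out: list[OutputRecord] = []
    for p in lists:
        rows = []
        for l in p.studied:
            rows.append(OutputRecord(
                item=l, list_id=p.list_id, in_encoding=True,
                in_recognition=l in set(p.targets), item_type=TYPE_STUDIED,
                distance=p.distance(space, l),
            ))
        for l in p.critical_lures:
            rows.append(OutputRecord(
                item=l, list_id=p.list_id, in_encoding=False,
                in_recognition=True, item_type=TYPE_CRITICAL,
                distance=p.distance(space, l),
            ))
        for l in p.unrelated_lures:
            rows.append(OutputRecord(
                item=l, list_id=p.list_id, in_encoding=False,
                in_recognition=True, item_type=TYPE_UNRELATED,
                distance=p.distance(space, l),
            ))
        rows.sort(key=lambda r: (r.distance, r.item))
        out.extend(rows)
    return out


def write_list_output(lists: list[DRMList], space: VectorSpace, path) -> None:
    """Write the list file: TSV, header row, distances to six decimals."""
    if not lists:
        raise ValidationError("no lists to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(LIST_HEADER) + "\n")
        for r in records_for(lists, space):
            fh.write(
                f"{r.item}\t{r.list_id}\t{int(r.in_encoding)}\t"
                f"{int(r.in_recognition)}\t{r.item_type}\t{r.distance:.6f}\n"
            )


def read_list_output(path) -> list[OutputRecord]:
    """Re-parse a list file written by :func:`write_list_output`."""
    records: list[OutputRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != LIST_HEADER:
            raise ValidationError(f"unexpected header {header!r}")
        for line in fh:
            item, lid, enc, rec, typ, dist = line.rstrip("\n").split("\t")
            records.append(OutputRecord(
                item=item, list_id=int(lid), in_encoding=bool(int(enc)),
                in_recognition=bool(int(rec)), item_type=typ,
                distance=float(dist),
            ))
    return records


def write_close_space_report(lists: list[DRMList], space: VectorSpace, path) -> None:
    """Write the close-space report.

    Per list: all close-space items (role Studied / Target / Critical Lure
    / Unselected) then that list's unrelated lures, each section ascending
    by distance to the list centroid.
    """
    if not lists:
        raise ValidationError("no lists to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("list\trank\titem\tregion\trole\tdistance\n")
        for p in lists:
            targets = set(p.targets)
            crit = set(p.critical_lures)
            studied = set(p.studied)
            rows = []
            for l in p.close_space:
                if l in targets:
                    role = "Target"
                elif l in studied:
                    role = TYPE_STUDIED
                elif l in crit:
                    role = TYPE_CRITICAL
                else:
                    role = "Unselected"
                rows.append((p.distance(space, l), l, "close", role))
            far_rows = [
                (p.distance(space, l), l, "far", TYPE_UNRELATED)
                for l in p.unrelated_lures
            ]
            rows.sort()
            far_rows.sort()
            for rank, (d, l, region, role) in enumerate(rows + far_rows, 1):
                fh.write(f"{p.list_id}\t{rank}\t{l}\t{region}\t{role}\t{d:.6f}\n")
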