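"""Data model and I/O for binary dominant-marker matrices.

Dominant fingerprinting assays (ISSR, RAPD, AFLP) score each gel band as a
presence/absence locus: a sample either shows the band (1) or does not (0),
and heterozygotes are indistinguishable from band-present homozygotes.  The
whole downstream analysis therefore runs on a single currency — a samples ×
loci 0/1 matrix with population labels and a locus → primer grouping —
represented here by :class:`MarkerMatrix`.

Missing scores are held as NaN internally and written as ``NA`` (plain TSV)
or ``-9`` (STRUCTURE format).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "GeoTable",
    "MarkerFormatError",
    "MarkerValidationError",
    "read_marker_matrix",
    "write_marker_matrix",
    "write_structure_file",
    "band_frequencies",
    "classify_loci",
]

MISSING = np.nan


class MarkerFormatError(ValueError):
    """A cell or header in an input file cannot be parsed."""


class MarkerValidationError(ValueError):
    """Parsed content violates a structural invariant."""


def _parse_cell(text: str, row: int, col: str) -> float:
    text = text.strip()
    if text in ("NA", "", "-9"):
        return MISSING
    if text == "0":
        return 0.0
    if text == "1":
        return 1.0
    raise MarkerFormatError(
        f"non-binary cell value {text!r} at sample row {row}, locus {col!r}; "
        "expected 0, 1 or NA"
    )


@dataclass
class MarkerMatrix:
    """Samples × loci binary band matrix with population and primer metadata.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample labels, in row order.
    pop_labels : list of str
        One population name per sample.
    locus_ids : list of str
        Unique locus (band) labels, in column order.
    primer_of_locus : dict
        Maps every locus id to the primer that produced it.
    bands : ndarray of shape (n_samples, n_loci)
        Values in {0, 1, NaN}; NaN marks a missing score.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    locus_ids: list[str]
    primer_of_locus: dict[str, str]
    bands: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        n, L = len(self.sample_ids), len(self.locus_ids)
        if len(set(self.sample_ids)) != n:
            dupes = [s for s in set(self.sample_ids) if self.sample_ids.count(s) > 1]
            raise MarkerValidationError(f"duplicate sample ids: {sorted(dupes)}")
        if len(self.pop_labels) != n:
            raise MarkerValidationError(
                f"{len(self.pop_labels)} population labels for {n} samples"
            )
        if len(set(self.locus_ids)) != L:
            raise MarkerValidationError("duplicate locus ids")
        if self.bands.shape != (n, L):
            raise MarkerValidationError(
                f"bands shape {self.bands.shape} != ({n}, {L})"
            )
        missing_primers = [l for l in self.locus_ids if l not in self.primer_of_locus]
        if missing_primers:
            raise MarkerValidationError(
                f"loci without a primer assignment: {missing_primers[:5]}"
            )
        vals = self.bands[~np.isnan(self.bands)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0))][0]
            raise MarkerValidationError(f"band values must be 0/1/missing, found {bad}")

    # -- convenience views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        """Population names in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    @property
    def pop_sizes(self) -> dict[str, int]:
        return {p: self.pop_labels.count(p) for p in self.populations}

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.pop_labels) == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return idx

    @property
    def primers(self) -> list[str]:
        """Primer names in order of first appearance along the loci."""
        seen: dict[str, None] = {}
        for l in self.locus_ids:
            seen.setdefault(self.primer_of_locus[l])
        return list(seen)

    def loci_of_primer(self, primer: str) -> list[str]:
        loci = [l for l in self.locus_ids if self.primer_of_locus[l] == primer]
        if not loci:
            raise KeyError(f"unknown primer {primer!r}")
        return loci

    def subset_samples(self, index: np.ndarray) -> "MarkerMatrix":
        return MarkerMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            pop_labels=[self.pop_labels[i] for i in index],
            locus_ids=list(self.locus_ids),
            primer_of_locus=dict(self.primer_of_locus),
            bands=self.bands[index],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bands, index=self.sample_ids, columns=self.locus_ids)
        df.insert(0, "pop", self.pop_labels)
        return df


@dataclass
class GeoTable:
    """Per-sample WGS84 coordinates in decimal degrees."""

    sample_ids: list[str]
    latitude: np.ndarray
    longitude: np.ndarray

    def __post_init__(self) -> None:
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        n = len(self.sample_ids)
        if self.latitude.shape != (n,) or self.longitude.shape != (n,):
            raise MarkerValidationError("coordinate arrays must match sample count")
        if np.any(np.abs(self.latitude) > 90):
            raise MarkerValidationError("latitude outside [-90, 90]")
        if np.any(np.abs(self.longitude) > 180):
            raise MarkerValidationError("longitude outside [-180, 180]")

    def check_against(self, m: MarkerMatrix) -> None:
        unknown = set(self.sample_ids) - set(m.sample_ids)
        if unknown:
            raise MarkerValidationError(
                f"GeoTable samples absent from marker matrix: {sorted(unknown)[:5]}"
            )

    @classmethod
    def read_tsv(cls, path) -> "GeoTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sample_ids=df.iloc[:, 0].astype(str).tolist(),
            latitude=df.iloc[:, 1].to_numpy(float),
            longitude=df.iloc[:, 2].to_numpy(float),
        )

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": self.sample_ids, "lat": self.latitude, "lon": self.longitude}
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O: plain TSV dialect
#
# row 1: "sample\tpop\t<locus ids...>"
# optional row starting "#primer": primer name per locus
# one row per sample; NA = missing
# ---------------------------------------------------------------------------

def _read_plain_tsv(path) -> MarkerMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "sample" or header[1] != "pop":
        raise MarkerFormatError(
            "plain TSV must start with a 'sample\\tpop\\t<loci...>' header"
        )
    locus_ids = header[2:]
    primer_of_locus: dict[str, str] = {}
    body = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if parts[0] == "#primer":
            primers = parts[2:]
            if len(primers) != len(locus_ids):
                raise MarkerFormatError(
                    f"#primer row lists {len(primers)} primers for {len(locus_ids)} loci"
                )
            primer_of_locus = dict(zip(locus_ids, primers))
        else:
            body.append(parts)
    if not primer_of_locus:
        # single anonymous primer when no grouping is given
        primer_of_locus = {l: "P1" for l in locus_ids}
    sample_ids, pop_labels, rows = [], [], []
    for r, parts in enumerate(body, start=1):
        if len(parts) != 2 + len(locus_ids):
            raise MarkerFormatError(
                f"sample row {r} has {len(parts)} fields, expected {2 + len(locus_ids)}"
            )
        sample_ids.append(parts[0])
        pop_labels.append(parts[1])
        rows.append([_parse_cell(c, r, locus_ids[j]) for j, c in enumerate(parts[2:])])
    return MarkerMatrix(sample_ids, pop_labels, locus_ids, primer_of_locus,
                        np.array(rows, dtype=float))


def _write_plain_tsv(m: MarkerMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tpop\t" + "\t".join(m.locus_ids) + "\n")
        fh.write("#primer\t\t" +
                 "\t".join(m.primer_of_locus[l] for l in m.locus_ids) + "\n")
        for i, sid in enumerate(m.sample_ids):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in m.bands[i]]
            fh.write(f"{sid}\t{m.pop_labels[i]}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# I/O: GenAlEx binary-CSV dialect
#
# row 1: n_loci, n_samples, n_pops, size_1, ..., size_K
# row 2: <title>,, pop_1, ..., pop_K
# row 3: Sample, Pop, <locus ids...>
# then one row per sample.  Metadata counts are cross-checked on read.
# ---------------------------------------------------------------------------

def _read_genalex_csv(path) -> MarkerMatrix:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(c.strip() for c in row)]
    if len(rows) < 4:
        raise MarkerFormatError("GenAlEx file needs 2 metadata rows, a header and data")
    try:
        meta = [int(x) for x in rows[0] if x.strip() != ""]
    except ValueError as exc:
        raise MarkerFormatError(f"GenAlEx metadata row 1 not integral: {rows[0]}") from exc
    n_loci, n_samples, n_pops, *sizes = meta
    header = rows[2]
    locus_ids = [c.strip() for c in header[2:] if c.strip() != ""]
    sample_ids, pop_labels, band_rows = [], [], []
    for r, row in enumerate(rows[3:], start=1):
        sample_ids.append(row[0].strip())
        pop_labels.append(row[1].strip())
        band_rows.append(
            [_parse_cell(c, r, locus_ids[j]) for j, c in enumerate(row[2:2 + len(locus_ids)])]
        )
    m = MarkerMatrix(sample_ids, pop_labels, locus_ids,
                     {l: "P1" for l in locus_ids}, np.array(band_rows, dtype=float))
    # cross-check declared metadata against parsed content
    if m.n_loci != n_loci or m.n_samples != n_samples:
        raise MarkerValidationError(
            f"GenAlEx metadata declares {n_samples}×{n_loci}, "
            f"file contains {m.n_samples}×{m.n_loci}"
        )
    if len(m.populations) != n_pops:
        raise MarkerValidationError(
            f"GenAlEx metadata declares {n_pops} populations, found {len(m.populations)}"
        )
    actual_sizes = [m.pop_sizes[p] for p in m.populations]
    if sizes and actual_sizes != sizes[: len(actual_sizes)]:
        raise MarkerValidationError(
            f"GenAlEx declared population sizes {sizes} != parsed {actual_sizes}"
        )
    return m


def _write_genalex_csv(m: MarkerMatrix, path, title: str = "dompop export") -> None:
    pops = m.populations
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([m.n_loci, m.n_samples, len(pops)] + [m.pop_sizes[p] for p in pops])
        w.writerow([title, ""] + pops)
        w.writerow(["Sample", "Pop"] + m.locus_ids)
        for i, sid in enumerate(m.sample_ids):
            cells = ["-9" if np.isnan(v) else int(v) for v in m.bands[i]]
            w.writerow([sid, m.pop_labels[i]] + cells)


def read_marker_matrix(path, dialect: str = "plain_tsv") -> MarkerMatrix:
    """Read a binary band matrix.

    ``dialect`` is ``plain_tsv`` (tab-separated, optional ``#primer`` row) or
    ``genalex_csv`` (GenAlEx binary layout with two metadata header rows that
    are cross-checked against the parsed content).
    """
    if dialect == "plain_tsv":
        return _read_plain_tsv(path)
    if dialect == "genalex_csv":
        return _read_genalex_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_marker_matrix(m: MarkerMatrix, path, dialect: str = "plain_tsv") -> None:
    if dialect == "plain_tsv":
        _write_plain_tsv(m, path)
    elif dialect == "genalex_csv":
        _write_genalex_csv(m, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_structure_file(m: MarkerMatrix, path) -> None:
    """Write a STRUCTURE input file: one row per (haploid) individual.

    Columns: sample label, integer population code, then one 0/1 column per
    locus with ``-9`` for missing.
    """
    pop_code = {p: k + 1 for k, p in enumerate(m.populations)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(" ".join(m.locus_ids) + "\n")
        for i, sid in enumerate(m.sample_ids):
            cells = ["-9" if np.isnan(v) else str(int(v)) for v in m.bands[i]]
            fh.write(f"{sid} {pop_code[m.pop_labels[i]]} " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Band frequencies and polymorphism classification
# ---------------------------------------------------------------------------

def band_frequencies(m: MarkerMatrix, scope: str = "pooled") -> pd.DataFrame:
    """Fraction of non-missing samples showing each band.

    Returns a DataFrame indexed by group (``pooled`` or one row per
    population) with one column per locus; a cell is NaN when the group has
    no scored sample at that locus.  A companion count of scored samples is
    attached as ``result.attrs["n_scored"]``.
    """
    scored = ~np.isnan(m.bands)
    present = np.nan_to_num(m.bands, nan=0.0)
    if scope == "pooled":
        groups = {"pooled": np.arange(m.n_samples)}
    elif scope == "per_population":
        groups = {p: m.pop_indices(p) for p in m.populations}
    else:
        raise ValueError(f"unknown scope {scope!r}")
    freqs, counts = {}, {}
    for name, idx in groups.items():
        if idx.size == 0:
            raise MarkerValidationError(f"empty group {name!r}")
        n = scored[idx].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, present[idx].sum(axis=0) / np.maximum(n, 1), np.nan)
        freqs[name] = p
        counts[name] = n
    out = pd.DataFrame(freqs, index=m.locus_ids).T
    out.attrs["n_scored"] = pd.DataFrame(counts, index=m.locus_ids).T
    return out


def classify_loci(m: MarkerMatrix, poly_criterion: float | None = None) -> pd.DataFrame:
    """Per-primer scored/polymorphic band counts.

    A locus is polymorphic iff its pooled band frequency p satisfies
    0 < p < 1 (strict criterion).  With ``poly_criterion=0.95`` the common
    "95% rule" is applied instead (polymorphic iff the commoner state has
    frequency ≤ 0.95).

    Returns a DataFrame with one row per primer plus a ``Total`` row and
    columns SB (scored bands), PB (polymorphic bands) and PPB (percent).
    Per-locus flags are attached as ``result.attrs["polymorphic"]``.
    """
    p = band_frequencies(m, "pooled").loc["pooled"].to_numpy()
    if poly_criterion is None:
        poly = (p > 0) & (p < 1)
    else:
        poly = np.minimum(p, 1 - p) > (1 - poly_criterion)
    rows = []
    for primer in m.primers:
        cols = [m.locus_ids.index(l) for l in m.loci_of_primer(primer)]
        sb, pb = len(cols), int(poly[cols].sum())
        rows.append({"primer": primer, "SB": sb, "PB": pb, "PPB": 100.0 * pb / sb})
    total_sb, total_pb = m.n_loci, int(poly.sum())
    rows.append({"primer": "Total", "SB": total_sb, "PB": total_pb,
                 "PPB": 100.0 * total_pb / total_sb})
    out = pd.DataFrame(rows).set_index("primer")
    out.attrs["polymorphic"] = pd.Series(poly, index=m.locus_ids)
    return out
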