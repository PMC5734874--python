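"""Readers and writers for the tab-separated dialects used by the pipeline.

All tables are UTF-8 TSV with a header row.  In mutation tables '-' or an
empty field denotes the absent side of a pure insertion/deletion.  Positions
are 1-based within the CDS.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
from Bio import SeqIO

from .accumulation import AccumulationPoint, LinearFit
from .gene_model import KDistribution
from .genome_counts import GenomeCountSet
from .saturation import FractionEstimate, SaturationEstimate
from .spectrum import MutationRecord, SpectrumSummary

PathLike = Union[str, Path]

MUTATION_COLUMNS = ["sample", "population", "day", "locus", "position", "ref", "alt"]


class InputError(ValueError):
    """A user-input problem, reported with file (and line) context."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_mutation_table(path: PathLike) -> list[MutationRecord]:
    """Read a mutation TSV (sample, population, day, locus, position, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, MUTATION_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MutationRecord(
                    sample_id=row.sample,
                    population_id=row.population,
                    day=float(row.day),
                    locus=row.locus,
                    position=int(row.position),
                    ref=row.ref,
                    alt=row.alt,
                )
            )
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path} line {i}: {exc}") from exc
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "population": r.population_id,
                "day": r.day,
                "locus": r.locus,
                "position": r.position,
                "ref": r.ref or "-",
                "alt": r.alt or "-",
            }
            for r in records
        ],
        columns=MUTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a (multi-)FASTA into {record id: uppercase sequence}."""
    seqs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise InputError(f"{path}: duplicate record id {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
    except FileNotFoundError:
        raise
    if not seqs:
        raise InputError(f"{path}: no FASTA records found")
    return seqs


def read_k_distribution(path: PathLike) -> KDistribution:
    """Read a TSV with columns i, k_i."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["i", "k_i"], path)
    try:
        counts = {int(row.i): int(row.k_i) for row in df.itertuples(index=False)}
        return KDistribution(counts)
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_k_distribution(kd: KDistribution, path: PathLike) -> None:
    pd.DataFrame(
        {"i": list(kd.counts), "k_i": list(kd.counts.values())}
    ).to_csv(path, sep="\t", index=False)


def _fmt(value) -> str:
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_spectrum_summary(summary: SpectrumSummary, path: PathLike) -> None:
    """Key/value TSV mirroring the spectrum report rows (ratios to 2 dp)."""
    rows = []
    for key, value in asdict(summary).items():
        if key in ("indel_size_histogram", "class_counts"):
            for sub, count in value.items():
                rows.append((f"{key}.{sub}", count))
        elif key in ("ts_tv_ratio",):
            rows.append((key, "NA" if math.isnan(value) else f"1:{value:.2f}"))
        elif isinstance(value, float):
            rows.append((key, "NA" if math.isnan(value) else f"{value:.2f}"))
        else:
            rows.append((key, value))
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        path, sep="\t", index=False
    )


def write_saturation_table(
    rows: Sequence[tuple[str, SaturationEstimate, FractionEstimate | None]],
    path: PathLike,
) -> None:
    """One row per (label, estimate, fraction): method, k_hat, CI, f."""
    out = []
    for label, est, frac in rows:
        out.append(
            {
                "label": label,
                "method": est.method,
                "k_hat": "NA" if est.k_hat is None else est.k_hat,
                "ci_lo": "NA" if est.ci95[0] is None else est.ci95[0],
                "ci_hi": "NA" if est.ci95[1] is None else est.ci95[1],
                "unbounded": est.unbounded,
                "f": "NA" if frac is None else f"{frac.f:.2f}",
                "f_lo": "NA" if frac is None else f"{frac.ci95[0]:.2f}",
                "f_hi": "NA" if frac is None else f"{frac.ci95[1]:.2f}",
            }
        )
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def write_likelihood_profile(ks, weights, path: PathLike) -> None:
    """Dump (k, normalized likelihood) for plotting."""
    pd.DataFrame({"k": ks, "likelihood": weights}).to_csv(path, sep="\t", index=False)


def read_accumulation_table(path: PathLike) -> list[AccumulationPoint]:
    """Read a TSV with columns experiment, day, frequency (class optional)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["experiment", "day", "frequency"], path)
    try:
        return [
            AccumulationPoint(float(r.day), float(r.frequency), str(r.experiment))
            for r in df.itertuples(index=False)
        ]
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_fit_table(fits: dict[str, LinearFit], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "class": label,
                "slope": f.slope,
                "intercept": f.intercept,
                "r2": f.r_squared,
                "n_points": f.n_points,
            }
            for label, f in fits.items()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_genome_counts(path: PathLike) -> list[int]:
    """Read per-genome counts: either one integer per line, or a TSV with a
    header containing a ``n_mutations`` column (genome_id, n_mutations)."""
    text = Path(path).read_text().strip()
    if not text:
        raise InputError(f"{path}: empty file")
    first = text.splitlines()[0]
    if "n_mutations" in first:
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, ["n_mutations"], path)
        values = df["n_mutations"].tolist()
    else:
        values = text.split()
    try:
        return [int(v) for v in values]
    except ValueError as exc:
        raise InputError(f"{path}: non-integer count: {exc}") from exc


def write_gof_table(result: GenomeCountSet, path: PathLike) -> None:
    rows = [
        ("n_genomes", result.n),
        ("lambda", _fmt(result.lambda_hat)),
        ("chi2", _fmt(result.chi2)),
        ("df", result.df),
        ("p_value", _fmt(result.p_value)),
        ("warning", result.warning or "NA"),
    ]
    rows += [
        (f"bin.{label}", f"{obs}|{exp:.3f}") for label, (obs, exp) in result.bins.items()
    ]
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        path, sep="\t", index=False
    )
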