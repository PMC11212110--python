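"""Domain samples, paired/unpaired dataset assembly, normalization, CSV I/O.

The central container is :class:`ImbalancedDataset`: a *source* (simulation)
collection and a *target* (real-world) collection of tabular samples sharing
the same covariate space, of which a small subset is *paired* — the same
covariate point observed in both domains.  The count identities

    n_source = n_paired + n_unpaired_source
    n_target = n_paired + n_unpaired_target

are enforced by construction.  Two views are exposed: ``paired_only`` (the
paired tuples, used by the targeted-regression fold) and ``all`` (every
sample once, used by the adversarial fold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Domain = Literal["sim", "real"]

#: covariate agreement tolerance inside a pair (paired samples share the
#: exact same experimental condition; anything beyond rounding is a bug)
PAIR_COVARIATE_TOL = 1e-9


@dataclass(frozen=True)
class DomainSample:
    """One observation: shared covariates, a scalar response, a domain tag."""

    covariates: tuple[float, ...]
    response: float
    domain: Domain
    pair_id: int | None = None

    def __post_init__(self) -> None:
        cov = tuple(float(c) for c in self.covariates)
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "response", float(self.response))
        if self.domain not in ("sim", "real"):
            raise ValueError(f"unknown domain tag {self.domain!r}")
        if not all(math.isfinite(c) for c in cov):
            raise ValueError("covariates must be finite")


@dataclass
class ImbalancedDataset:
    """Paired + unpaired source + unpaired target samples.

    ``paired`` holds (sim, real) tuples observed at identical covariates;
    ``unpaired_source`` are simulation-only samples ("have y1 no y2");
    ``unpaired_target`` are real-world-only samples ("have y2 no y1").
    """

    paired: list[tuple[DomainSample, DomainSample]] = field(default_factory=list)
    unpaired_source: list[DomainSample] = field(default_factory=list)
    unpaired_target: list[DomainSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, r in self.paired:
            if s.domain != "sim" or r.domain != "real":
                raise ValueError("paired tuples must be (sim, real)")
            if len(s.covariates) != len(r.covariates) or any(
                abs(a - b) > PAIR_COVARIATE_TOL
                for a, b in zip(s.covariates, r.covariates)
            ):
                raise ValueError("paired samples must share covariates")
        if any(s.domain != "sim" for s in self.unpaired_source):
            raise ValueError("unpaired_source must be sim samples")
        if any(s.domain != "real" for s in self.unpaired_target):
            raise ValueError("unpaired_target must be real samples")

    # -- counts ---------------------------------------------------------
    @property
    def n_paired(self) -> int:
        return len(self.paired)

    @property
    def n_source(self) -> int:
        return len(self.paired) + len(self.unpaired_source)

    @property
    def n_target(self) -> int:
        return len(self.paired) + len(self.unpaired_target)

    @property
    def n_covariates(self) -> int:
        for s in self.source_samples():
            return len(s.covariates)
        for s in self.unpaired_target:
            return len(s.covariates)
        return 0

    # -- sample access --------------------------------------------------
    def source_samples(self) -> list[DomainSample]:
        """All simulation samples, paired first (stable order)."""
        return [s for s, _ in self.paired] + list(self.unpaired_source)

    def target_samples(self) -> list[DomainSample]:
        """All real-world samples, paired first (stable order)."""
        return [r for _, r in self.paired] + list(self.unpaired_target)

    def view(
        self, which: Literal["paired_only", "all"]
    ) -> list[tuple[DomainSample, DomainSample]] | list[DomainSample]:
        return dataset_view(self, which)


def dataset_view(
    ds: ImbalancedDataset, which: Literal["paired_only", "all"]
) -> list[tuple[DomainSample, DomainSample]] | list[DomainSample]:
    """``paired_only``: the paired (sim, real) tuples; ``all``: every sample once."""
    if which == "paired_only":
        return list(ds.paired)
    if which == "all":
        return ds.source_samples() + ds.target_samples()
    raise ValueError(f"unknown view {which!r}; expected 'paired_only' or 'all'")


def assemble_dataset(
    source: Sequence[DomainSample],
    target: Sequence[DomainSample],
    pairing: Sequence[tuple[int, int]],
) -> ImbalancedDataset:
    """Segment source/target samples into paired and unpaired partitions.

    ``pairing`` lists (source_index, target_index) tuples; indices must be
    unique per side and the two members of a pair must share covariates.
    """
    src_idx = [i for i, _ in pairing]
    tgt_idx = [j for _, j in pairing]
    if len(set(src_idx)) != len(src_idx) or len(set(tgt_idx)) != len(tgt_idx):
        raise ValueError("pairing indices must be unique per side")
    for i in src_idx:
        if not 0 <= i < len(source):
            raise IndexError(f"source pairing index {i} out of range")
    for j in tgt_idx:
        if not 0 <= j < len(target):
            raise IndexError(f"target pairing index {j} out of range")

    paired: list[tuple[DomainSample, DomainSample]] = []
    for pid, (i, j) in enumerate(pairing):
        s, r = source[i], target[j]
        if s.domain != "sim":
            raise ValueError(f"source sample {i} is not a sim sample")
        if r.domain != "real":
            raise ValueError(f"target sample {j} is not a real sample")
        if len(s.covariates) != len(r.covariates) or any(
            abs(a - b) > PAIR_COVARIATE_TOL for a, b in zip(s.covariates, r.covariates)
        ):
            raise ValueError(
                f"covariate mismatch within pair (source {i}, target {j})"
            )
        paired.append((replace(s, pair_id=pid), replace(r, pair_id=pid)))

    unpaired_source = [
        replace(s, pair_id=None) for i, s in enumerate(source) if i not in set(src_idx)
    ]
    unpaired_target = [
        replace(r, pair_id=None) for j, r in enumerate(target) if j not in set(tgt_idx)
    ]
    return ImbalancedDataset(paired, unpaired_source, unpaired_target)


# ----------------------------------------------------------------------
# Normalization
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NormStats:
    """Per-feature z-scoring statistics fitted on a training partition.

    Covariates share one location/scale across domains (paired covariates are
    identical by construction); responses are scaled per domain because the
    two domains can live on very different scales.
    """

    cov_loc: np.ndarray
    cov_scale: np.ndarray
    resp_loc: dict[str, float]
    resp_scale: dict[str, float]

    def normalize_cov(self, cov: np.ndarray) -> np.ndarray:
        return (np.asarray(cov, dtype=float) - self.cov_loc) / self.cov_scale

    def denormalize_cov(self, cov: np.ndarray) -> np.ndarray:
        return np.asarray(cov, dtype=float) * self.cov_scale + self.cov_loc

    def normalize_resp(self, resp: np.ndarray, domain: Domain) -> np.ndarray:
        return (np.asarray(resp, dtype=float) - self.resp_loc[domain]) / self.resp_scale[domain]

    def denormalize_resp(self, resp: np.ndarray, domain: Domain) -> np.ndarray:
        return np.asarray(resp, dtype=float) * self.resp_scale[domain] + self.resp_loc[domain]


def fit_normalizer(ds: ImbalancedDataset) -> NormStats:
    """Fit z-scoring stats (population scale) on the training partitions.

    Raises on zero-variance features, naming the offending feature.
    """
    src = ds.source_samples()
    tgt = ds.target_samples()
    if not src or not tgt:
        raise ValueError("both domains must be non-empty to fit a normalizer")
    cov = np.array([s.covariates for s in src + tgt], dtype=float)
    cov_loc = cov.mean(axis=0)
    cov_scale = cov.std(axis=0)
    for k, sc in enumerate(cov_scale):
        if sc <= 0:
            raise ValueError(f"zero-variance covariate x{k + 1}")
    resp_loc, resp_scale = {}, {}
    for domain, samples in (("sim", src), ("real", tgt)):
        y = np.array([s.response for s in samples], dtype=float)
        loc, sc = float(y.mean()), float(y.std())
        if sc <= 0:
            raise ValueError(f"zero-variance response in domain {domain!r}")
        resp_loc[domain], resp_scale[domain] = loc, sc
    return NormStats(cov_loc, cov_scale, resp_loc, resp_scale)


def apply_normalizer(
    stats: NormStats, samples: Iterable[DomainSample]
) -> list[DomainSample]:
    out = []
    for s in samples:
        cov = stats.normalize_cov(np.array(s.covariates))
        y = float(stats.normalize_resp(np.array(s.response), s.domain))
        out.append(replace(s, covariates=tuple(cov), response=y))
    return out


def invert_normalizer(
    stats: NormStats, samples: Iterable[DomainSample]
) -> list[DomainSample]:
    out = []
    for s in samples:
        cov = stats.denormalize_cov(np.array(s.covariates))
        y = float(stats.denormalize_resp(np.array(s.response), s.domain))
        out.append(replace(s, covariates=tuple(cov), response=y))
    return out


# ----------------------------------------------------------------------
# CSV round trip
# ----------------------------------------------------------------------
# Dialect: comma-separated, mandatory header, UTF-8, '.' decimal.  Columns:
# covariate names..., response, domain, pair_id (blank = unpaired).

def write_samples_csv(samples: Sequence[DomainSample], path, covariate_names=None) -> None:
    if samples:
        d = len(samples[0].covariates)
    else:
        d = 0
    names = list(covariate_names) if covariate_names else [f"x{i + 1}" for i in range(d)]
    rows = []
    for s in samples:
        row = {n: c for n, c in zip(names, s.covariates)}
        row["response"] = s.response
        row["domain"] = s.domain
        row["pair_id"] = "" if s.pair_id is None else s.pair_id
        rows.append(row)
    df = pd.DataFrame(rows, columns=names + ["response", "domain", "pair_id"])
    df.to_csv(path, index=False)


def read_samples_csv(path) -> list[DomainSample]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"response", "domain", "pair_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    cov_names = [c for c in df.columns if c not in required]
    samples: list[DomainSample] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, after the header line
        domain = row["domain"].strip()
        if domain not in ("sim", "real"):
            raise ValueError(f"row {rowno}: unknown domain tag {domain!r}")
        try:
            cov = tuple(float(row[c]) for c in cov_names)
            resp = float(row["response"])
        except ValueError as exc:
            raise ValueError(f"row {rowno}: non-numeric field ({exc})") from None
        pid_raw = row["pair_id"].strip()
        pid = int(pid_raw) if pid_raw else None
        samples.append(DomainSample(cov, resp, domain, pid))
    return samples


def write_dataset_csv(ds: ImbalancedDataset, path, covariate_names=None) -> None:
    """One flat CSV for a whole dataset; pair membership carried by pair_id."""
    samples = ds.source_samples() + ds.target_samples()
    write_samples_csv(samples, path, covariate_names)


def read_dataset_csv(path) -> ImbalancedDataset:
    """Rebuild an :class:`ImbalancedDataset` from a flat CSV via pair_id links."""
    samples = read_samples_csv(path)
    by_pid: dict[int, dict[str, DomainSample]] = {}
    unpaired_source, unpaired_target = [], []
    for s in samples:
        if s.pair_id is None:
            (unpaired_source if s.domain == "sim" else unpaired_target).append(s)
        else:
            slot = by_pid.setdefault(s.pair_id, {})
            if s.domain in slot:
                raise ValueError(f"pair_id {s.pair_id} repeated within domain {s.domain}")
            slot[s.domain] = s
    paired = []
    for pid in sorted(by_pid):
        slot = by_pid[pid]
        if set(slot) != {"sim", "real"}:
            raise ValueError(f"pair_id {pid} must appear once per domain")
        paired.append((slot["sim"], slot["real"]))
    return ImbalancedDataset(paired, unpaired_source, unpaired_target)
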