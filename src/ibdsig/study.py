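"""Labeled expression study container, label schemes, splitting and TSV I/O.

The on-disk layout mirrors the study matrix orientation used throughout the
pipeline: samples are columns; the first four rows carry the per-sample
covariates (``label``, ``age``, ``sex``, ``region``) and every remaining row
is one gene. Everything downstream (screening, classification, the Monte
Carlo search) consumes the genes-by-samples matrix stored here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .util import round_half_up

__all__ = [
    "RAW_CLASSES",
    "REGIONS",
    "ExpressionStudy",
    "LabelScheme",
    "CONTROL_VS_IBD",
    "UC_VS_CD",
    "SplitIndices",
    "StudyError",
    "DuplicateIdError",
    "RaggedRowError",
    "NonNumericValueError",
    "UnknownRegionError",
    "UnknownLabelError",
    "SingleClassError",
    "encode_labels",
    "split_train_test",
    "read_study",
    "write_study",
    "write_split",
    "read_split",
]

#: The three raw diagnostic classes.
RAW_CLASSES = ("control", "UC", "CD")

#: The seven biopsy areas, in fixed order (integer codes 0-6 follow this order).
REGIONS = (
    "Rectum",
    "Left colon",
    "Right colon",
    "Ileum",
    "Transverse",
    "Sigmoid",
    "Cecum",
)

_HEADER_ROWS = ("label", "age", "sex", "region")


class StudyError(ValueError):
    """Base class for study validation and parsing errors."""


class DuplicateIdError(StudyError):
    pass


class RaggedRowError(StudyError):
    pass


class NonNumericValueError(StudyError):
    pass


class UnknownRegionError(StudyError):
    pass


class UnknownLabelError(StudyError):
    pass


class SingleClassError(StudyError):
    """Raised when a label scheme leaves only one class: classification is undefined."""


@dataclass
class ExpressionStudy:
    """A labeled expression matrix with per-sample covariates.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene names, one per matrix row (length ``m``).
    expression : ndarray, shape (m, n)
        Real-valued expression, genes as rows, samples as columns.
    labels : ndarray of str, length n
        Raw diagnostic class per sample, each in :data:`RAW_CLASSES`.
    age : ndarray of int, length n
        Age in years, positive.
    sex : ndarray of int, length n
        0 = female, 1 = male.
    region : ndarray of str, length n
        Biopsy area, each in :data:`REGIONS`.
    sample_ids : list of str
        Unique sample names (length ``n``).
    """

    gene_ids: list[str]
    expression: np.ndarray
    labels: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    region: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.age = np.asarray(self.age, dtype=int)
        self.sex = np.asarray(self.sex, dtype=int)
        self.region = np.asarray(self.region, dtype=object)
        m, n = self.n_genes, self.n_samples
        if m < 1 or n < 2:
            raise StudyError(f"need m >= 1 genes and n >= 2 samples, got m={m}, n={n}")
        if self.expression.shape != (m, n):
            raise StudyError(
                f"expression shape {self.expression.shape} does not match "
                f"{m} genes x {n} samples"
            )
        for name, vec in (("labels", self.labels), ("age", self.age),
                          ("sex", self.sex), ("region", self.region)):
            if len(vec) != n:
                raise StudyError(f"{name} has length {len(vec)}, expected {n}")
        if len(set(self.gene_ids)) != m:
            raise DuplicateIdError("gene_ids contain duplicates")
        if len(set(self.sample_ids)) != n:
            raise DuplicateIdError("sample_ids contain duplicates")
        if not np.all(np.isfinite(self.expression)):
            raise StudyError("expression contains non-finite values")
        for j, lab in enumerate(self.labels):
            if lab not in RAW_CLASSES:
                raise UnknownLabelError(
                    f"sample {self.sample_ids[j]!r}: unknown class label {lab!r}"
                )
        for j, reg in enumerate(self.region):
            if reg not in REGIONS:
                raise UnknownRegionError(
                    f"sample {self.sample_ids[j]!r}: unknown biopsy region {reg!r}"
                )
        if np.any(self.age <= 0):
            raise StudyError("ages must be positive integers")
        if not np.all(np.isin(self.sex, (0, 1))):
            raise StudyError("sex codes must be 0 (female) or 1 (male)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def region_codes(self) -> np.ndarray:
        """Regions as integer codes 0-6 in the fixed :data:`REGIONS` order."""
        lookup = {r: i for i, r in enumerate(REGIONS)}
        return np.array([lookup[r] for r in self.region], dtype=int)


_EXCLUDE = None  # sentinel inside scheme mappings


@dataclass(frozen=True)
class LabelScheme:
    """Maps raw classes to a binary task; ``None`` drops the sample.

    The two study tasks: ``control_vs_ibd`` codes control as 0 and both IBD
    forms as 1; ``uc_vs_cd`` codes UC as 0, CD (the positive class) as 1 and
    excludes controls.
    """

    name: str
    mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.mapping) != set(RAW_CLASSES):
            raise StudyError("scheme mapping must cover control, UC and CD")
        codes = {v for v in self.mapping.values() if v is not None}
        if not codes.issubset({0, 1}):
            raise StudyError("scheme codes must be 0, 1 or None (exclude)")

    @staticmethod
    def from_name(name: str) -> "LabelScheme":
        try:
            return {s.name: s for s in (CONTROL_VS_IBD, UC_VS_CD)}[name]
        except KeyError:
            raise StudyError(f"unknown label scheme {name!r}") from None


CONTROL_VS_IBD = LabelScheme("control_vs_ibd", {"control": 0, "UC": 1, "CD": 1})
UC_VS_CD = LabelScheme("uc_vs_cd", {"control": None, "UC": 0, "CD": 1})


def encode_labels(study: ExpressionStudy, scheme: LabelScheme) -> tuple[np.ndarray, np.ndarray]:
    """Binary label vector for a task, plus the kept sample indices.

    Samples mapped to the exclusion sentinel are dropped; order is preserved.
    Raises :class:`SingleClassError` if fewer than two classes remain.
    """
    y, kept = [], []
    for j, lab in enumerate(study.labels):
        if lab not in scheme.mapping:
            raise UnknownLabelError(
                f"sample {study.sample_ids[j]!r}: unknown class label {lab!r}"
            )
        code = scheme.mapping[lab]
        if code is _EXCLUDE:
            continue
        y.append(code)
        kept.append(j)
    y_arr = np.asarray(y, dtype=int)
    if len(set(y)) < 2:
        raise SingleClassError(
            f"scheme {scheme.name!r} leaves a single class among kept samples; "
            "classification is undefined"
        )
    return y_arr, np.asarray(kept, dtype=int)


@dataclass(frozen=True)
class SplitIndices:
    """A train/test partition of the eligible sample indices."""

    train: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        train = np.asarray(self.train, dtype=int)
        test = np.asarray(self.test, dtype=int)
        object.__setattr__(self, "train", train)
        object.__setattr__(self, "test", test)
        if set(train) & set(test):
            raise StudyError("train and test indices overlap")


def split_train_test(
    study: ExpressionStudy,
    kept: np.ndarray,
    fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> SplitIndices:
    """Randomized train/test split of the kept samples.

    ``|train| = round(fraction * n_kept)`` (half away from zero). By default
    the split is stratified on the raw class so both halves see every class;
    ``stratify=False`` restores a simple random split. Deterministic given
    ``seed``.
    """
    kept = np.asarray(kept, dtype=int)
    n = len(kept)
    if n < 2:
        raise StudyError("need at least 2 kept samples to split")
    if not 0.0 < fraction < 1.0:
        raise StudyError(f"fraction must be in (0, 1), got {fraction}")
    n_train = round_half_up(fraction * n)
    n_train = min(max(n_train, 1), n - 1)  # both halves non-empty
    rng = np.random.default_rng(seed)

    if not stratify:
        perm = rng.permutation(n)
        train = kept[np.sort(perm[:n_train])]
        test = kept[np.sort(perm[n_train:])]
        return SplitIndices(train=train, test=test, seed=seed)

    classes = [lab for lab in RAW_CLASSES if lab in set(study.labels[kept])]
    members = {c: kept[np.array([study.labels[k] == c for k in kept])] for c in classes}
    sizes = np.array([len(members[c]) for c in classes])
    quotas = fraction * sizes
    alloc = np.floor(quotas).astype(int)
    short = n_train - int(alloc.sum())
    order = np.lexsort((np.arange(len(classes)), -(quotas - alloc)))
    for i in order[:short]:
        alloc[i] += 1
    # guarantee each class lands in both halves where its size allows
    for i, c in enumerate(classes):
        if alloc[i] == 0 and sizes[i] >= 1:
            alloc[i] = 1
        if alloc[i] == sizes[i] and sizes[i] >= 2:
            alloc[i] -= 1
    # restore the exact train size by nudging the least-constrained classes
    while alloc.sum() > n_train:
        cand = [i for i in range(len(classes)) if alloc[i] > 1] or \
               [i for i in range(len(classes)) if alloc[i] > 0]
        i = max(cand, key=lambda i: (alloc[i], -i))
        alloc[i] -= 1
    while alloc.sum() < n_train:
        cand = [i for i in range(len(classes)) if alloc[i] < sizes[i] - 1] or \
               [i for i in range(len(classes)) if alloc[i] < sizes[i]]
        i = max(cand, key=lambda i: (sizes[i] - alloc[i], -i))
        alloc[i] += 1

    train_parts, test_parts = [], []
    for i, c in enumerate(classes):
        pool = members[c]
        perm = rng.permutation(len(pool))
        train_parts.append(pool[perm[: alloc[i]]])
        test_parts.append(pool[perm[alloc[i]:]])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return SplitIndices(train=train, test=test, seed=seed)


# ---------------------------------------------------------------------------
# TSV serialization (samples as columns; covariate rows then gene rows)

def write_study(study: ExpressionStudy, path: str | Path) -> None:
    """Write a study as UTF-8 TSV; ``read_study`` inverts it exactly.

    Expression values are written with ``repr`` so the float round-trip is
    bit-identical.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", *study.sample_ids])
        w.writerow(["label", *study.labels])
        w.writerow(["age", *(str(int(a)) for a in study.age)])
        w.writerow(["sex", *(str(int(s)) for s in study.sex)])
        w.writerow(["region", *study.region])
        for i, gid in enumerate(study.gene_ids):
            w.writerow([gid, *(repr(float(v)) for v in study.expression[i])])


def read_study(path: str | Path) -> ExpressionStudy:
    """Parse a study TSV written by :func:`write_study`.

    Distinct errors are raised for ragged rows, duplicate ids, non-numeric
    cells and unknown region strings, each naming the offending row/column.
    """
    path = Path(path)
    with path.open("r", newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if len(rows) < 6:
        raise StudyError("study file needs a header, 4 covariate rows and >= 1 gene row")
    header = rows[0]
    if header[0] != "sample_id":
        raise StudyError(f"first cell must be 'sample_id', got {header[0]!r}")
    sample_ids = header[1:]
    n = len(sample_ids)
    if len(set(sample_ids)) != n:
        raise DuplicateIdError("duplicate sample id in header row")

    named = {}
    for r, expected in enumerate(_HEADER_ROWS, start=1):
        row = rows[r]
        if row[0] != expected:
            raise StudyError(
                f"row {r + 1} must be {expected!r} (fixed order label/age/sex/region), "
                f"got {row[0]!r}"
            )
        if len(row) != n + 1:
            raise RaggedRowError(
                f"row {expected!r} has {len(row) - 1} values, expected {n}"
            )
        named[expected] = row[1:]

    def _ints(name: str, cells: list[str]) -> np.ndarray:
        out = []
        for j, c in enumerate(cells):
            try:
                out.append(int(c))
            except ValueError:
                raise NonNumericValueError(
                    f"row {name!r}, column {sample_ids[j]!r}: non-numeric value {c!r}"
                ) from None
        return np.asarray(out, dtype=int)

    age = _ints("age", named["age"])
    sex = _ints("sex", named["sex"])
    for j, reg in enumerate(named["region"]):
        if reg not in REGIONS:
            raise UnknownRegionError(
                f"row 'region', column {sample_ids[j]!r}: unknown region {reg!r}"
            )

    gene_ids, data = [], []
    for r in range(5, len(rows)):
        row = rows[r]
        if not row:
            continue
        gid = row[0]
        if len(row) != n + 1:
            raise RaggedRowError(
                f"gene row {gid!r} has {len(row) - 1} values, expected {n}"
            )
        vals = []
        for j, c in enumerate(row[1:]):
            try:
                vals.append(float(c))
            except ValueError:
                raise NonNumericValueError(
                    f"gene row {gid!r}, column {sample_ids[j]!r}: "
                    f"non-numeric expression value {c!r}"
                ) from None
        gene_ids.append(gid)
        data.append(vals)
    if len(set(gene_ids)) != len(gene_ids):
        seen, dup = set(), None
        for g in gene_ids:
            if g in seen:
                dup = g
                break
            seen.add(g)
        raise DuplicateIdError(f"duplicate gene id {dup!r}")

    return ExpressionStudy(
        gene_ids=gene_ids,
        expression=np.asarray(data, dtype=float),
        labels=np.asarray(named["label"], dtype=object),
        age=age,
        sex=sex,
        region=np.asarray(named["region"], dtype=object),
        sample_ids=sample_ids,
    )


def write_split(split: SplitIndices, sample_ids: list[str], path: str | Path) -> None:
    """Serialize a split as a (sample_id, partition) CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["sample_id", "partition"])
        for i in split.train:
            w.writerow([sample_ids[i], "train"])
        for i in split.test:
            w.writerow([sample_ids[i], "test"])


def read_split(path: str | Path, sample_ids: list[str], seed: int = -1) -> SplitIndices:
    lookup = {s: i for i, s in enumerate(sample_ids)}
    train, test = [], []
    with Path(path).open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["sample_id", "partition"]:
            raise StudyError("split file must have header sample_id,partition")
        for sid, part in reader:
            if sid not in lookup:
                raise StudyError(f"split references unknown sample {sid!r}")
            (train if part == "train" else test).append(lookup[sid])
    return SplitIndices(train=np.asarray(train), test=np.asarray(test), seed=seed)
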