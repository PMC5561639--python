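"""Mulan-dialect multi-label dataset I/O.

A Mulan dataset is a pair of files: a dense Weka ARFF file carrying *all*
attributes (features and labels mixed), and an XML manifest naming which
attributes are labels.  This module reads such a pair into a validated
:class:`MultiLabelDataset` and writes one back so that a write-then-read
round trip is exact.

Only the dense dialect is supported: numeric attributes and two-valued
nominal attributes with domain ``{0,1}``.  Anything else (strings, dates,
wider nominal domains, sparse rows, missing values) is rejected loudly at
load time rather than silently coerced.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import arff as _scipy_arff

__all__ = [
    "MultiLabelDataset",
    "SchemaError",
    "ValidationError",
    "read_mulan",
    "write_mulan",
]

MULAN_XMLNS = "http://mulan.sourceforge.net/labels"


class SchemaError(ValueError):
    """The XML label manifest and the ARFF attributes disagree."""


class ValidationError(ValueError):
    """The dataset content violates the supported dialect."""


@dataclass
class MultiLabelDataset:
    """An in-memory multi-label dataset.

    Attributes
    ----------
    features : (n, p) float64 array
        Numeric feature matrix; {0,1}-nominal ARFF features are coerced.
    labels : (n, m) int64 array of {0,1}
        Binary label matrix, columns in XML-manifest order.
    feature_names, label_names : list of str
        Attribute names; disjoint, each internally unique.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    label_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def m(self) -> int:
        return self.labels.shape[1]

    def validate(self) -> "MultiLabelDataset":
        if self.features.ndim != 2 or self.labels.ndim != 2:
            raise ValidationError("features and labels must be 2-D matrices")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValidationError(
                f"row mismatch: {self.features.shape[0]} feature rows vs "
                f"{self.labels.shape[0]} label rows"
            )
        if self.p < 1:
            raise ValidationError("need at least one feature attribute (p >= 1)")
        if self.m < 1:
            raise ValidationError("need at least one label attribute (m >= 1)")
        if len(self.feature_names) != self.p or len(self.label_names) != self.m:
            raise ValidationError("attribute-name lists do not match matrix widths")
        names = self.feature_names + self.label_names
        if len(set(names)) != len(names):
            raise ValidationError("feature and label names must be disjoint and unique")
        if not np.isin(self.labels, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.labels, (0, 1)))[0]
            raise ValidationError(
                f"label matrix contains non-binary value "
                f"{self.labels[bad[0], bad[1]]!r} at row {bad[0]}, "
                f"column {self.label_names[bad[1]]!r}"
            )
        if not np.isfinite(self.features).all():
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise ValidationError(
                f"non-finite feature value at row {bad[0]}, "
                f"column {self.feature_names[bad[1]]!r}"
            )
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiLabelDataset):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and self.label_names == other.label_names
            and self.features.shape == other.features.shape
            and self.labels.shape == other.labels.shape
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
        )


def _read_label_names(xml_path: str | Path) -> list[str]:
    try:
        tree = ET.parse(xml_path)
    except FileNotFoundError:
        raise
    except ET.ParseError as exc:
        raise SchemaError(f"cannot parse label XML {xml_path}: {exc}") from exc
    names: list[str] = []
    for el in tree.getroot().iter():
        if el.tag.rsplit("}", 1)[-1] == "label":
            name = el.get("name")
            if name is None:
                raise SchemaError(f"<label> element without a name in {xml_path}")
            names.append(name)
    if not names:
        raise ValidationError(f"label XML {xml_path} names zero labels (m >= 1 required)")
    if len(set(names)) != len(names):
        raise SchemaError(f"duplicate label names in {xml_path}")
    return names


def _is_binary_nominal(values: tuple[str, ...] | None) -> bool:
    return values is not None and set(values) == {"0", "1"}


def read_mulan(arff_path: str | Path, xml_path: str | Path) -> MultiLabelDataset:
    """Read a Mulan ``.arff`` + ``.xml`` pair.

    Attributes named by the XML manifest become label columns (in XML
    order); every remaining attribute becomes a feature column (in ARFF
    order).  Raises :class:`SchemaError` when the two files disagree and
    :class:`ValidationError` for unsupported content.
    """
    label_names = _read_label_names(xml_path)
    try:
        data, meta = _scipy_arff.loadarff(str(arff_path))
    except FileNotFoundError:
        raise
    except _scipy_arff.ParseArffError as exc:
        raise ValidationError(f"cannot parse ARFF {arff_path}: {exc}") from exc

    attr_names = list(meta.names())
    for lab in label_names:
        if lab not in attr_names:
            raise SchemaError(
                f"label {lab!r} from {xml_path} has no matching attribute in {arff_path}"
            )
    label_set = set(label_names)
    feature_names = [a for a in attr_names if a not in label_set]
    if not feature_names:
        raise ValidationError("ARFF has no feature attributes left after label split")

    n = data.shape[0]

    def _column(name: str, as_label: bool) -> np.ndarray:
        kind, values = meta[name]
        col = data[name]
        if kind == "nominal":
            if not _is_binary_nominal(tuple(values)):
                raise ValidationError(
                    f"attribute {name!r} has nominal domain {tuple(values)}; "
                    "only {0,1} is supported"
                )
            raw = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in col])
            if (raw == "?").any():
                row = int(np.nonzero(raw == "?")[0][0])
                raise ValidationError(f"missing value in attribute {name!r} at row {row}")
            return raw.astype(np.int64)
        if kind == "numeric":
            out = np.asarray(col, dtype=np.float64)
            if np.isnan(out).any():
                row = int(np.nonzero(np.isnan(out))[0][0])
                raise ValidationError(f"missing value in attribute {name!r} at row {row}")
            if as_label:
                if not np.isin(out, (0.0, 1.0)).all():
                    row = int(np.nonzero(~np.isin(out, (0.0, 1.0)))[0][0])
                    raise ValidationError(
                        f"label {name!r} has non-binary value {out[row]!r} at row {row}"
                    )
                return out.astype(np.int64)
            return out
        raise ValidationError(
            f"attribute {name!r} has unsupported type {kind!r} "
            "(only numeric and {0,1}-nominal)"
        )

    features = (
        np.column_stack([_column(f, as_label=False) for f in feature_names])
        if n
        else np.empty((0, len(feature_names)))
    )
    labels = (
        np.column_stack([_column(l, as_label=True) for l in label_names])
        if n
        else np.empty((0, len(label_names)), dtype=np.int64)
    )
    features = np.asarray(features, dtype=np.float64).reshape(n, len(feature_names))
    labels = np.asarray(labels, dtype=np.int64).reshape(n, len(label_names))
    return MultiLabelDataset(features, labels, feature_names, label_names).validate()


def _fmt(value: float) -> str:
    # repr(float) round-trips exactly through float(), keeping write/read lossless
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(float(value))


def write_mulan(
    dataset: MultiLabelDataset,
    arff_path: str | Path,
    xml_path: str | Path,
    relation: str = "multilabel",
) -> None:
    """Write ``dataset`` as a Mulan ``.arff`` + ``.xml`` pair.

    Labels are written as nominal ``{0,1}`` attributes after the features,
    so ``read_mulan`` on the output reproduces the dataset exactly.
    """
    dataset.validate()
    buf = io.StringIO()
    buf.write(f"@relation {relation}\n\n")
    for name in dataset.feature_names:
        buf.write(f"@attribute {name} numeric\n")
    for name in dataset.label_names:
        buf.write(f"@attribute {name} {{0,1}}\n")
    buf.write("\n@data\n")
    for i in range(dataset.n):
        row = [_fmt(v) for v in dataset.features[i]]
        row += [str(int(v)) for v in dataset.labels[i]]
        buf.write(",".join(row) + "\n")
    Path(arff_path).write_text(buf.getvalue())

    root = ET.Element("labels", {"xmlns": MULAN_XMLNS})
    for name in dataset.label_names:
        ET.SubElement(root, "label", {"name": name})
    ET.ElementTree(root).write(xml_path, encoding="unicode", xml_declaration=True)
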