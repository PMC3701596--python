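"""Difference-vector heatmap ordering and pipeline data products.

For every probe strict-labeled in both tissues, an 8-dimensional vector of
sleep-minus-deprived mean log2 differences is built — (heart, lung) x
times (3, 6, 9, 12) — and ordered by agglomerative clustering (Euclidean
distance) purely to place similar trajectories adjacently in the exported
heatmap matrix.  ``export_products`` writes every stage's tables plus a
reproducibility manifest with input checksums.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .study import DesignError, ExpressionStudy

log = logging.getLogger(__name__)


def diff_vectors(studies: dict, labels_by_tissue: dict) -> pd.DataFrame:
    """Sleep-minus-deprived mean difference vectors for shared strict probes.

    ``studies`` maps tissue to its :class:`ExpressionStudy`;
    ``labels_by_tissue`` maps tissue to a strict-label table.  Entries are
    ``mean(sleep) - mean(deprived)`` per (tissue, time) in log2 units
    (positive = higher in sleep), columns ordered tissue-major by
    ascending time.  Only probes strict-labeled in *both* tissues appear;
    an empty intersection yields an empty table.
    """
    if len(studies) < 2:
        raise DesignError("difference vectors need two analysed tissues")
    strict_sets = []
    for tissue, tab in labels_by_tissue.items():
        strict_sets.append(set(tab.index[tab["label"] != "unclassified"]))
    shared = sorted(set.intersection(*strict_sets))
    columns = {}
    for tissue, study in studies.items():
        sub = study.resolve_tissue(tissue).subset(arms=("sleep", "deprived"))
        times = np.sort(sub.samples.loc[sub.samples["time_h"] > 0, "time_h"].unique())
        probe_pos = pd.Index(sub.probe_ids).get_indexer(shared)
        if len(shared) and (probe_pos < 0).any():
            raise DesignError("strict probes missing from the expression matrix")
        for t in times:
            s_mask = ((sub.samples["arm"] == "sleep") & (sub.samples["time_h"] == t)).to_numpy()
            d_mask = ((sub.samples["arm"] == "deprived") & (sub.samples["time_h"] == t)).to_numpy()
            if not s_mask.any() or not d_mask.any():
                raise DesignError(f"missing ({tissue}, t={t}) cell")
            diff = sub.values[:, s_mask].mean(axis=1) - sub.values[:, d_mask].mean(axis=1)
            columns[f"{tissue}_t{int(t)}"] = diff[probe_pos] if len(shared) else []
    return pd.DataFrame(columns, index=pd.Index(shared, name="probe_id"))


def agglomerative_order(vectors: pd.DataFrame, metric: str = "euclidean",
                        method: str = "average") -> list:
    """Dendrogram leaf order of the difference vectors.

    Clustering is presentational only — it orders rows so that similar
    vectors are adjacent.  Deterministic given input order (scipy's
    tie-breaking by input index).
    """
    if method not in ("single", "complete", "average"):
        raise ValueError("method must be one of single/complete/average")
    if len(vectors) == 0:
        return []
    if len(vectors) == 1:
        return [vectors.index[0]]
    z = linkage(pdist(vectors.to_numpy(), metric=metric), method=method)
    return [vectors.index[i] for i in leaves_list(z)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def export_products(outdir, tables: dict, manifest_extra: dict | None = None) -> dict:
    """Write every table as TSV plus a ``manifest.txt`` with checksums.

    ``tables`` maps a product name to a DataFrame (written as
    ``<name>.tsv``).  The manifest records package/library versions, any
    extra key-value context (config, seeds), and the sha256 of every file
    written — rerunning with the same inputs gives byte-identical
    products.  Returns ``{name: path}``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise SystemExit(f"output directory {outdir} is not writable: {exc}")
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", float_format="%.10g")
        paths[name] = path
    import periphsleep
    lines = [f"periphsleep_version\t{periphsleep.__version__}",
             f"numpy_version\t{np.__version__}",
             f"pandas_version\t{pd.__version__}"]
    for key, value in (manifest_extra or {}).items():
        lines.append(f"{key}\t{value}")
    for name in sorted(paths):
        lines.append(f"sha256:{paths[name].name}\t{_sha256(paths[name])}")
    (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")
    paths["manifest"] = outdir / "manifest.txt"
    log.info("wrote %d products to %s", len(paths), outdir)
    return paths
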