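"""End-to-end study orchestration.

``run_study`` wires the stages together: simulate a cohort, register each
patient's image pair once (intensity-only — the same field serves every
reader), build per-reader response records, and compute the full agreement
and survival-association report:

- spatial overlap (GCI) of pancreas and tumor segmentations by reader
  group and timepoint, with Wilcoxon signed-rank comparisons;
- concordance (OCCC) of size measurements and of the six longitudinal
  response indexes, with junior-vs-senior Z-tests;
- Fleiss' kappa of RECIST/WHO response categories under each index score;
- reader-vs-pathology diameter bias and concordance;
- Harrell's C-index of every index against OS and RFS.

Registration fields are cached on disk keyed by a content hash of the
image pair and parameters, so re-running an analysis stage does not redo
the expensive stage upstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import agreement, response
from .agreement import AgreementResult, bootstrap_ci, ccc_bands, ccc_z_test, fleiss_kappa, gci, harrell_c, occc
from .config import StudyConfig
from .imaging import SurvivalRecord, mask_volume
from .registration import DeformationField, RegistrationParams, register
from .synthetic import Cohort, generate_cohort

__all__ = ["StudyReport", "run_study", "compute_fields", "pathology_bias", "survival_association"]

logger = logging.getLogger("regresponse")

GROUPS = ("junior", "senior", "all")

SIZE_QUANTITIES = [
    "v_pancreas_pre",
    "v_pancreas_post",
    "pct_dv_pancreas",
    "v_tumor_pre",
    "v_tumor_post_seg",
    "pct_dv_seg",
    "sdp_pre",
    "sdp_post",
    "pct_dsdp",
    "sld_pre",
    "sld_post",
    "pct_dsld",
]

INDEX_QUANTITIES = ["pct_dsld", "pct_dsdp", "pct_dv_seg", "db_seg", "pct_dv_reg", "db_reg"]

KAPPA_CRITERIA = ["recist_sld", "who_sdp", "recist_vseg", "recist_vreg"]


@dataclass
class StudyReport:
    """All tables of one study run (every cell recomputable from records)."""

    config: StudyConfig
    records: pd.DataFrame
    truth: pd.DataFrame
    gci_values: pd.DataFrame  # patient_id, structure, timepoint, group, gci
    gci_summary: pd.DataFrame  # structure, timepoint, group, mean, sd
    gci_tests: pd.DataFrame  # comparison, group, timepoint, p
    size_ccc: pd.DataFrame  # quantity, group, ccc, ci_low, ci_high, band, p_junior_vs_senior
    index_ccc: pd.DataFrame  # same for the six longitudinal indexes
    kappa: pd.DataFrame  # criterion, group, kappa, ci_low, ci_high
    pathology: dict  # mean bias and per-group CCC vs pathology
    cindex: pd.DataFrame  # index, endpoint, c_mean, c_sd, ci_low, ci_high
    timings: dict = dataclass_field(default_factory=dict)

    def lookup_ccc(self, quantity: str, group: str) -> float:
        frame = self.index_ccc if quantity in INDEX_QUANTITIES else self.size_ccc
        row = frame[(frame.quantity == quantity) & (frame.group == group)]
        if len(row) != 1:
            raise KeyError(f"no CCC cell for {quantity}/{group}")
        return float(row.ccc.iloc[0])

    def lookup_kappa(self, criterion: str, group: str) -> float:
        row = self.kappa[(self.kappa.criterion == criterion) & (self.kappa.group == group)]
        if len(row) != 1:
            raise KeyError(f"no kappa cell for {criterion}/{group}")
        return float(row.kappa.iloc[0])

    def write(self, outdir: str | Path, plots: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "response_records.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.gci_values.to_csv(outdir / "gci.csv", index=False)
        self.gci_summary.to_csv(outdir / "gci_summary.csv", index=False)
        self.gci_tests.to_csv(outdir / "gci_tests.csv", index=False)
        self.size_ccc.to_csv(outdir / "size_ccc.csv", index=False)
        self.index_ccc.to_csv(outdir / "index_ccc.csv", index=False)
        self.kappa.to_csv(outdir / "kappa.csv", index=False)
        self.cindex.to_csv(outdir / "cindex.csv", index=False)
        summary = {
            "seed": self.config.seed,
            "n_patients": self.config.n_patients,
            "pathology": self.pathology,
            "timings_s": self.timings,
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=2, default=float))
        self.config.to_json(outdir / "config.json")
        if plots:
            _write_plots(self, outdir / "plots")


# ---------------------------------------------------------------------------
# registration stage
# ---------------------------------------------------------------------------


def _pair_hash(cohort_patient, params: RegistrationParams) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(cohort_patient.truth.pre_image.voxels).tobytes())
    h.update(np.ascontiguousarray(cohort_patient.truth.post_image.voxels).tobytes())
    h.update(repr(params).encode())
    return h.hexdigest()[:16]


def compute_fields(
    cohort: Cohort,
    params: RegistrationParams | None = None,
    cache_dir: str | Path | None = None,
) -> dict[str, DeformationField]:
    """One unsupervised registration per patient (fixed = restaging scan).

    With ``cache_dir`` set, fields are memoized on disk keyed by a content
    hash of the image pair and parameters.
    """
    params = params or RegistrationParams()
    fields: dict[str, DeformationField] = {}
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    for p in cohort.patients:
        t0 = time.perf_counter()
        path = cache / f"{p.patient_id}_{_pair_hash(p, params)}.npz" if cache else None
        if path is not None and path.exists():
            data = np.load(path)
            fields[p.patient_id] = DeformationField(
                data["displacement"], tuple(data["spacing"]), tuple(data["origin"])
            )
            continue
        field = register(p.truth.post_image, p.truth.pre_image, params)
        fields[p.patient_id] = field
        if path is not None:
            np.savez_compressed(
                path,
                displacement=field.displacement,
                spacing=np.asarray(field.spacing),
                origin=np.asarray(field.origin),
            )
        logger.info("registered %s in %.1fs", p.patient_id, time.perf_counter() - t0)
    return fields


# ---------------------------------------------------------------------------
# agreement tables
# ---------------------------------------------------------------------------


def _group_readers(cohort: Cohort, group: str) -> list[str]:
    return cohort.reader_ids(None if group == "all" else group)


def _reader_matrix(records: pd.DataFrame, quantity: str, reader_ids: Sequence[str]) -> np.ndarray:
    wide = records.pivot(index="patient_id", columns="reader_id", values=quantity)
    return wide[list(reader_ids)].to_numpy()


def _gci_tables(cohort: Cohort, seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    rows = []
    for p in cohort.patients:
        for structure in ("pancreas", "tumor"):
            for tp in ("pre", "post"):
                masks = {
                    rid: (
                        p.annotations[(rid, tp)].pancreas_mask
                        if structure == "pancreas"
                        else p.annotations[(rid, tp)].tumor_mask
                    )
                    for rid in cohort.reader_ids()
                }
                for group in GROUPS:
                    rids = _group_readers(cohort, group)
                    rows.append(
                        {
                            "patient_id": p.patient_id,
                            "structure": structure,
                            "timepoint": tp,
                            "group": group,
                            "gci": gci([masks[r] for r in rids]),
                        }
                    )
    values = pd.DataFrame(rows)
    summary = (
        values.groupby(["structure", "timepoint", "group"])["gci"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"std": "sd"})
    )

    def paired(sel_a: dict, sel_b: dict) -> float:
        a = values.loc[(values[list(sel_a)] == pd.Series(sel_a)).all(axis=1)].sort_values("patient_id")
        b = values.loc[(values[list(sel_b)] == pd.Series(sel_b)).all(axis=1)].sort_values("patient_id")
        d = a.gci.to_numpy() - b.gci.to_numpy()
        if np.all(d == 0):
            return float("nan")
        return agreement.wilcoxon_signed_rank(d)

    tests = []
    for group in GROUPS:
        for tp in ("pre", "post"):
            tests.append(
                {
                    "comparison": "tumor_vs_pancreas",
                    "group": group,
                    "timepoint": tp,
                    "p": paired(
                        {"structure": "tumor", "timepoint": tp, "group": group},
                        {"structure": "pancreas", "timepoint": tp, "group": group},
                    ),
                }
            )
        for structure in ("pancreas", "tumor"):
            tests.append(
                {
                    "comparison": f"{structure}_pre_vs_post",
                    "group": group,
                    "timepoint": "both",
                    "p": paired(
                        {"structure": structure, "timepoint": "pre", "group": group},
                        {"structure": structure, "timepoint": "post", "group": group},
                    ),
                }
            )
    for structure in ("pancreas", "tumor"):
        for tp in ("pre", "post"):
            tests.append(
                {
                    "comparison": f"junior_vs_senior_{structure}",
                    "group": "junior/senior",
                    "timepoint": tp,
                    "p": paired(
                        {"structure": structure, "timepoint": tp, "group": "junior"},
                        {"structure": structure, "timepoint": tp, "group": "senior"},
                    ),
                }
            )
    return values, summary, pd.DataFrame(tests)


def _ccc_table(
    cohort: Cohort,
    records: pd.DataFrame,
    quantities: Sequence[str],
    reps: int,
    seed: int,
) -> pd.DataFrame:
    rows = []
    for q_idx, quantity in enumerate(quantities):
        mats = {g: _reader_matrix(records, quantity, _group_readers(cohort, g)) for g in GROUPS}
        try:
            z, p_js = ccc_z_test(
                mats["junior"], mats["senior"], paired_subjects=True, reps=reps, seed=seed + q_idx
            )
        except ValueError:
            p_js = float("nan")
        for group in GROUPS:
            data = mats[group]
            value = occc(data)
            lo, hi = bootstrap_ci(occc, data, reps=reps, seed=seed + 100 + q_idx)
            rows.append(
                {
                    "quantity": quantity,
                    "group": group,
                    "ccc": value,
                    "ci_low": min(lo, value),
                    "ci_high": max(hi, value),
                    "band": ccc_bands(value),
                    "p_junior_vs_senior": p_js,
                }
            )
    return pd.DataFrame(rows)


def _kappa_table(cohort: Cohort, records: pd.DataFrame, reps: int, seed: int) -> pd.DataFrame:
    rows = []
    for c_idx, criterion in enumerate(KAPPA_CRITERIA):
        for group in GROUPS:
            rids = _group_readers(cohort, group)
            wide = records.pivot(index="patient_id", columns="reader_id", values=criterion)
            result = fleiss_kappa(
                wide[rids].to_numpy(),
                categories=response.CATEGORIES,
                reps=reps,
                seed=seed + c_idx,
            )
            rows.append(
                {
                    "criterion": criterion,
                    "group": group,
                    "kappa": result.value,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "degenerate": bool(result.metadata.get("degenerate", False)),
                }
            )
    return pd.DataFrame(rows)


def pathology_bias(
    records: pd.DataFrame, truth: pd.DataFrame, cohort: Cohort, reps: int = 1000, seed: int = 0
) -> dict:
    """Reader restaging diameters vs ground-truth pathology diameters.

    Returns the mean signed bias (reader minus pathology, mm) with a
    t-based 95% CI over all annotations, and per-group concordance of the
    reader diameters with pathology.
    """
    from scipy import stats as sps

    merged = records.merge(truth[["patient_id", "pathology_diameter_mm"]], on="patient_id")
    diffs = (merged.sld_post - merged.pathology_diameter_mm).to_numpy()
    n = len(diffs)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    out = {
        "mean_bias_mm": mean,
        "sd_mm": sd,
        "ci_low_mm": mean - half,
        "ci_high_mm": mean + half,
        "n_annotations": n,
        "groups": {},
    }
    patho = truth.sort_values("patient_id").pathology_diameter_mm.to_numpy()
    for group in GROUPS:
        rids = _group_readers(cohort, group)
        mat = _reader_matrix(records, "sld_post", rids)
        data = np.column_stack([mat, patho])
        value = occc(data)
        lo, hi = bootstrap_ci(occc, data, reps=reps, seed=seed)
        out["groups"][group] = {"ccc_vs_pathology": value, "ci_low": min(lo, value), "ci_high": max(hi, value)}
    return out


def survival_association(
    records: pd.DataFrame,
    survival: Sequence[SurvivalRecord],
    truth: pd.DataFrame,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Harrell's C of each longitudinal index (and the true burden change)
    against each survival endpoint.

    Scores follow the risk convention: a larger index (growth) predicts
    shorter survival.  Per-reader C values are averaged; the CI is a
    subject-level bootstrap of that reader-averaged C.
    """
    surv = pd.DataFrame([{"patient_id": r.patient_id, "endpoint": r.endpoint, "time": r.time, "event": r.event} for r in survival])
    rows = []
    reader_ids = sorted(records.reader_id.unique())
    truth_sorted = truth.sort_values("patient_id")
    for endpoint in ("OS", "RFS"):
        end = surv[surv.endpoint == endpoint].sort_values("patient_id")
        times = end.time.to_numpy()
        events = end.event.to_numpy()
        for index in INDEX_QUANTITIES + ["true_db"]:
            if index == "true_db":
                score_mat = truth_sorted.true_db.to_numpy()[:, None]
            else:
                score_mat = _reader_matrix(records, index, reader_ids)

            def mean_c(block: np.ndarray) -> float:
                t, e = block[:, 0], block[:, 1].astype(int)
                cs = [harrell_c(block[:, 2 + j], (t, e)) for j in range(block.shape[1] - 2)]
                return float(np.mean(cs))

            block = np.column_stack([times, events, score_mat])
            per_reader = [harrell_c(score_mat[:, j], (times, events)) for j in range(score_mat.shape[1])]
            c_mean = float(np.mean(per_reader))
            lo, hi = bootstrap_ci(mean_c, block, reps=reps, seed=seed)
            rows.append(
                {
                    "index": index,
                    "endpoint": endpoint,
                    "c_mean": c_mean,
                    "c_sd": float(np.std(per_reader, ddof=1)) if len(per_reader) > 1 else 0.0,
                    "ci_low": min(lo, c_mean),
                    "ci_high": max(hi, c_mean),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _records_frame(cohort: Cohort, fields: Mapping[str, DeformationField]) -> pd.DataFrame:
    recs = response.build_response_records(cohort.annotation_mapping(), dict(fields))
    frame = response.records_to_frame(recs)
    frame["pct_dv_pancreas"] = (frame.v_pancreas_post - frame.v_pancreas_pre) / frame.v_pancreas_pre * 100.0
    return frame


def run_study(
    config: StudyConfig,
    outdir: str | Path | None = None,
    registration_params: RegistrationParams | None = None,
    cohort: Cohort | None = None,
    plots: bool = True,
) -> StudyReport:
    """Execute the full pipeline and return (and optionally write) the report.

    ``cohort`` may be passed to reuse an existing simulation (it must match
    ``config``); otherwise one is generated.  Deterministic for a fixed
    config: every bootstrap seed is derived from ``config.seed``.
    """
    timings = {}
    t0 = time.perf_counter()
    if cohort is None:
        cohort = generate_cohort(config)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cache_dir = Path(outdir) / "cache" if outdir else None
    fields = compute_fields(cohort, registration_params, cache_dir)
    timings["register"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    records = _records_frame(cohort, fields)
    truth = cohort.truth_frame()
    timings["measure"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reps = config.bootstrap_reps
    seed = config.seed
    gci_values, gci_summary, gci_tests = _gci_tables(cohort, seed)
    size_ccc = _ccc_table(cohort, records, SIZE_QUANTITIES, reps, seed)
    index_ccc = _ccc_table(cohort, records, INDEX_QUANTITIES, reps, seed + 1000)
    kappa = _kappa_table(cohort, records, reps, seed + 2000)
    patho = pathology_bias(records, truth, cohort, reps=reps, seed=seed + 3000)
    cindex = survival_association(records, cohort.survival, truth, reps=reps, seed=seed + 4000)
    timings["agree"] = time.perf_counter() - t0

    report = StudyReport(
        config=config,
        records=records,
        truth=truth,
        gci_values=gci_values,
        gci_summary=gci_summary,
        gci_tests=gci_tests,
        size_ccc=size_ccc,
        index_ccc=index_ccc,
        kappa=kappa,
        pathology=patho,
        cindex=cindex,
        timings=timings,
    )
    if outdir is not None:
        report.write(outdir, plots=plots)
    return report


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def _write_plots(report: StudyReport, plotdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir.mkdir(parents=True, exist_ok=True)

    # GCI distributions (pancreas/tumor x pre/post x group)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, structure in zip(axes, ("pancreas", "tumor")):
        sub = report.gci_values[report.gci_values.structure == structure]
        data, labels = [], []
        for tp in ("pre", "post"):
            for group in GROUPS:
                data.append(sub[(sub.timepoint == tp) & (sub.group == group)].gci.to_numpy())
                labels.append(f"{tp}\n{group}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(f"{structure} segmentation")
        ax.set_ylabel("GCI")
    fig.tight_layout()
    fig.savefig(plotdir / "gci.png", dpi=120)
    plt.close(fig)

    # CCC of longitudinal indexes by group
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.25
    x = np.arange(len(INDEX_QUANTITIES))
    for g_idx, group in enumerate(GROUPS):
        vals = [report.lookup_ccc(q, group) for q in INDEX_QUANTITIES]
        ax.bar(x + (g_idx - 1) * width, vals, width, label=group)
    ax.set_xticks(x)
    ax.set_xticklabels(INDEX_QUANTITIES, rotation=30, ha="right")
    ax.set_ylabel("CCC")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(plotdir / "index_ccc.png", dpi=120)
    plt.close(fig)

    # Harrell C per index and endpoint
    fig, ax = plt.subplots(figsize=(8, 4))
    idxs = list(report.cindex["index"].unique())
    x = np.arange(len(idxs))
    for e_idx, endpoint in enumerate(("OS", "RFS")):
        sub = report.cindex[report.cindex.endpoint == endpoint].set_index("index").loc[idxs]
        ax.bar(x + (e_idx - 0.5) * 0.4, sub.c_mean, 0.4, yerr=sub.c_sd, label=endpoint, capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(idxs, rotation=30, ha="right")
    ax.axhline(0.5, color="k", lw=0.5, ls="--")
    ax.set_ylabel("Harrell C")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plotdir / "cindex.png", dpi=120)
    plt.close(fig)
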