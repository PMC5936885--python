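"""File formats, configuration and the end-to-end pipeline.

Everything the pipeline consumes and emits is plain text: transcription and
lexicon TSVs, beat and vowel-onset tables (TSV), observation exports (CSV,
one row per labelled interbeat duration), PCM WAV audio, TOML run
configuration, and a minimal subset of ELAN's EAF XML (one time-aligned
annotation tier) for beat tables exchanged with transcription tools.

:func:`run_pipeline` ties the stages together — segment → align → IBD →
statistics → distinctiveness — and writes a report bundle with a
provenance record (package version, seed, configuration hash), so identical
configurations yield identical reports.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from scipy.io import wavfile

from . import __version__
from .beats import (
    BeatEvent,
    IBDObservation,
    align_beats,
    detect_beats,
)
from .grammar import homophone_classes
from .phonology import Phrase, Word, segment_v_to_v, tone_pattern
from .stats import (
    ModelSpec,
    backward_select,
    consistency_score,
    derive_scale,
    pairwise_contrasts,
)
from .synth import (
    DEFAULT_DRUMMERS,
    DurationModel,
    generate_drummed_corpus,
    generate_lexicon,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_transcriptions",
    "read_lexicon",
    "write_segmentation",
    "read_beat_table",
    "write_beat_table",
    "read_onset_table",
    "read_wav",
    "write_wav",
    "read_beat_tier_eaf",
    "write_beat_tier_eaf",
    "export_observations",
    "read_observations",
    "run_pipeline",
]

#: Stable column order of the observation CSV export.
OBSERVATION_COLUMNS = [
    "duration_s", "vtov", "syllable", "mora", "vlen",
    "drummer", "speech_type", "intra_word",
]
_FRAME_TO_CSV = {
    "duration_s": "duration_s", "vtov_label": "vtov",
    "syllable_label": "syllable", "mora_label": "mora",
    "vlen_label": "vlen", "drummer_id": "drummer",
    "speech_type": "speech_type", "intra_word": "intra_word",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


# ---------------------------------------------------------------------------
# Tables


def read_transcriptions(path) -> pd.DataFrame:
    """Transcription TSV: word_id, transcription, [gloss,] phrase_position."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"word_id", "transcription"}
    if not required <= set(df.columns):
        raise ValueError(f"transcription TSV needs columns {sorted(required)}")
    if "phrase_position" not in df.columns:
        df["phrase_position"] = "final"
    return df


def read_lexicon(path) -> list[Word]:
    """Lexicon TSV (word_id, transcription, ...) as tokenized words."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [Word(t) for t in df["transcription"]]


def write_segmentation(words: Sequence[Word | str], path) -> pd.DataFrame:
    """Per-word segmentation under every hypothesis, as TSV.

    Columns: word_id, unit_index, hypothesis ∈ {syllable, vtov, mora, vlen},
    content, type_label, weight.
    """
    rows = []
    for wi, w in enumerate(words):
        w = Word(w) if isinstance(w, str) else w
        for i, s in enumerate(w.syllables):
            rows.append((wi, i, "syllable", str(s), s.type_label,
                         s.weight_moras))
            rows.append((wi, i, "mora", str(s), str(s.weight_moras),
                         s.weight_moras))
        _, intervals = segment_v_to_v(w)
        for i, iv in enumerate(intervals):
            rows.append((wi, i, "vtov", str(iv), iv.type_label,
                         2 if iv.nucleus.long else 1))
            vlen = "long" if iv.nucleus.long else "short"
            rows.append((wi, i, "vlen", str(iv.nucleus), vlen,
                         2 if iv.nucleus.long else 1))
    df = pd.DataFrame(
        rows, columns=["word_id", "unit_index", "hypothesis", "content",
                       "type_label", "weight"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_beat_table(path) -> pd.DataFrame:
    """Beat table TSV with columns time_s, [pitch_hz,] [tone_label]."""
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError("beat table needs a time_s column")
    return df


def write_beat_table(beats, path) -> None:
    if not isinstance(beats, pd.DataFrame):
        beats = pd.DataFrame(
            {
                "time_s": [b.time_s for b in beats],
                "pitch_hz": [b.pitch_hz for b in beats],
                "tone_label": [b.tone_label for b in beats],
            }
        )
    beats.to_csv(path, sep="\t", index=False)


def beat_events(table: pd.DataFrame) -> list[BeatEvent]:
    """Materialise a beat table as events."""
    return [
        BeatEvent(
            time_s=float(r["time_s"]),
            pitch_hz=(float(r["pitch_hz"])
                      if "pitch_hz" in table.columns and pd.notna(r.get("pitch_hz"))
                      else None),
            tone_label=(r["tone_label"]
                        if "tone_label" in table.columns and pd.notna(r.get("tone_label"))
                        else None),
        )
        for _, r in table.iterrows()
    ]


def read_onset_table(path) -> np.ndarray:
    """Vowel-onset TSV (vowel_index, time_s) → times sorted by index."""
    df = pd.read_csv(path, sep="\t")
    if not {"vowel_index", "time_s"} <= set(df.columns):
        raise ValueError("onset table needs columns vowel_index, time_s")
    return df.sort_values("vowel_index")["time_s"].to_numpy(dtype=float)


def export_observations(observations, path) -> pd.DataFrame:
    """One CSV row per observation, stable column order, UTF-8."""
    if isinstance(observations, pd.DataFrame):
        df = observations.rename(columns=_FRAME_TO_CSV)
    else:
        df = pd.DataFrame(
            [
                {csv: getattr(o, attr)
                 for attr, csv in _FRAME_TO_CSV.items()}
                for o in observations
            ],
            columns=OBSERVATION_COLUMNS,
        )
    df = df.reindex(columns=OBSERVATION_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")
    return df


def read_observations(path) -> pd.DataFrame:
    """Read an observation CSV back into the internal frame layout."""
    df = pd.read_csv(
        path, encoding="utf-8",
        dtype={"drummer": str, "speech_type": str},
    )
    inv = {v: k for k, v in _FRAME_TO_CSV.items()}
    return df.rename(columns=inv)


# ---------------------------------------------------------------------------
# Audio


def read_wav(path) -> tuple[np.ndarray, int]:
    """Mono float waveform in [-1, 1] plus sample rate."""
    sr, data = wavfile.read(path)
    x = np.asarray(data, dtype=np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        x = x / float(np.iinfo(np.asarray(data).dtype).max)
    return x, int(sr)


def write_wav(path, audio: np.ndarray, sample_rate: int) -> None:
    wavfile.write(path, sample_rate, np.asarray(audio, dtype=np.float32))


# ---------------------------------------------------------------------------
# Minimal EAF (ELAN XML) support


def read_beat_tier_eaf(
    path,
    tier_id: str | None = None,
    point: Literal["start", "midpoint"] = "start",
) -> pd.DataFrame:
    """Read one time-aligned annotation tier of an EAF file as a beat table.

    Annotation values H/L become tone labels; times come from the linked
    time slots (milliseconds), taken at the annotation start or midpoint.
    Raises on malformed XML, a missing time-aligned tier, or unlinked time
    slots.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed EAF XML: {e}") from e
    root = tree.getroot()
    slots = {}
    for ts in root.iter("TIME_SLOT"):
        val = ts.get("TIME_VALUE")
        slots[ts.get("TIME_SLOT_ID")] = (
            None if val is None else int(val) / 1000.0
        )
    tiers = [
        t for t in root.iter("TIER")
        if (tier_id is None or t.get("TIER_ID") == tier_id)
        and t.find(".//ALIGNABLE_ANNOTATION") is not None
    ]
    if not tiers:
        raise ValueError("no time-aligned annotation tier found")
    rows = []
    for ann in tiers[0].iter("ALIGNABLE_ANNOTATION"):
        t1 = slots.get(ann.get("TIME_SLOT_REF1"))
        t2 = slots.get(ann.get("TIME_SLOT_REF2"))
        if t1 is None or t2 is None:
            raise ValueError(
                f"annotation {ann.get('ANNOTATION_ID')} references unlinked "
                "time slots"
            )
        value = (ann.findtext("ANNOTATION_VALUE") or "").strip()
        time = t1 if point == "start" else (t1 + t2) / 2.0
        rows.append(
            {"time_s": time,
             "tone_label": value if value in ("H", "L") else None,
             "pitch_hz": np.nan}
        )
    return pd.DataFrame(rows, columns=["time_s", "pitch_hz", "tone_label"])


def write_beat_tier_eaf(
    beats, path, tier_id: str = "beats", annotation_ms: int = 10
) -> None:
    """Write a beat table as a single-tier EAF (1 ms time resolution)."""
    if not isinstance(beats, pd.DataFrame):
        beats = pd.DataFrame(
            {"time_s": [b.time_s for b in beats],
             "tone_label": [b.tone_label for b in beats]}
        )
    root = etree.Element("ANNOTATION_DOCUMENT", VERSION="3.0")
    order = etree.SubElement(root, "TIME_ORDER")
    tier = etree.SubElement(root, "TIER", TIER_ID=tier_id,
                            LINGUISTIC_TYPE_REF="beat")
    for i, row in beats.reset_index(drop=True).iterrows():
        ms = int(round(float(row["time_s"]) * 1000))
        id1, id2 = f"ts{2 * i + 1}", f"ts{2 * i + 2}"
        etree.SubElement(order, "TIME_SLOT", TIME_SLOT_ID=id1,
                         TIME_VALUE=str(ms))
        etree.SubElement(order, "TIME_SLOT", TIME_SLOT_ID=id2,
                         TIME_VALUE=str(ms + annotation_ms))
        ann = etree.SubElement(etree.SubElement(tier, "ANNOTATION"),
                               "ALIGNABLE_ANNOTATION",
                               ANNOTATION_ID=f"a{i + 1}",
                               TIME_SLOT_REF1=id1, TIME_SLOT_REF2=id2)
        val = etree.SubElement(ann, "ANNOTATION_VALUE")
        tone = row.get("tone_label")
        val.text = tone if isinstance(tone, str) else ""
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass(frozen=True)
class RunConfig:
    """Reproducible pipeline run: paths, seed and analysis policy."""

    out_dir: str = "manguare_out"
    seed: int = 0
    alpha: float = 0.05
    multiplicity: Literal["max-t", "holm"] = "max-t"
    include_cross_word: bool = False
    include_vv: bool = False
    slip_policy: Literal["exclude", "keep"] = "exclude"
    report_units: str = "ms"
    observations_csv: str | None = None
    lexicon_tsv: str | None = None
    synth_n_medial_words: int = 170
    synth_n_final_words: int = 60
    synth_n_messages: int = 260
    synth_slip_rate: float = 0.05

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                for k, v in value.items():
                    flat[f"{key}_{k}"] = v
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"[{name}] {e}") from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute segment → align → IBD → statistics → distinctiveness.

    Observations are read from ``observations_csv`` when given, otherwise a
    synthetic drummed corpus is generated under the run seed.  The report
    bundle (ANOVA tables, contrast tables, scale strings, consistency and
    homophone reports, provenance) is written into ``out_dir`` and returned
    as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unit_scale = 1000.0 if config.report_units == "ms" else 1.0

    @_stage("input")
    def obtain_observations():
        if config.observations_csv:
            if not Path(config.observations_csv).exists():
                raise FileNotFoundError(config.observations_csv)
            df = read_observations(config.observations_csv)
            lexicon = (read_lexicon(config.lexicon_tsv)
                       if config.lexicon_tsv else None)
            return df, lexicon, None
        medial = generate_lexicon(config.synth_n_medial_words,
                                  seed=config.seed, position="medial")
        final = generate_lexicon(config.synth_n_final_words,
                                 seed=config.seed + 1, position="final")
        corpus = generate_drummed_corpus(
            {"medial": medial, "final": final},
            drummers=DEFAULT_DRUMMERS,
            duration_model=DurationModel(),
            n_messages=config.synth_n_messages,
            seed=config.seed + 2,
            slip_rate=config.synth_slip_rate,
        )
        df = corpus.frame(
            intra_word_only=not config.include_cross_word,
            exclude_vv=not config.include_vv,
        )
        lexicon = (read_lexicon(config.lexicon_tsv)
                   if config.lexicon_tsv else list(medial) + list(final))
        return df, lexicon, corpus

    df, lexicon, corpus = obtain_observations()
    export_observations(df, out / "observations.csv")

    @_stage("stats")
    def run_stats():
        bundle = {}
        for unit in ("vtov", "syllable"):
            fitted, log = backward_select(
                df, ModelSpec(unit=unit), alpha=config.alpha
            )
            contrasts = pairwise_contrasts(
                fitted, alpha=config.alpha, method=config.multiplicity,
                seed=config.seed + 1000,
            )
            scales = {
                g: str(derive_scale(contrasts, group=g))
                for g in sorted({r.group for r in contrasts.results})
            }
            fitted.anova.to_csv(out / f"anova_{unit}.csv")
            contrasts.frame().to_csv(out / f"contrasts_{unit}.csv",
                                     index=False)
            bundle[unit] = {
                "formula": fitted.formula,
                "adj_r2": fitted.adj_r2,
                "n_contrasts": len(contrasts),
                "n_significant": sum(
                    r.significant for r in contrasts.results
                ),
                "scales": scales,
                "cell_means_" + config.report_units: {
                    f"{g}:{t}": m * unit_scale
                    for (g, t), m in contrasts.cell_means.items()
                },
            }
            if unit == "syllable":
                bundle["consistency"] = {
                    hyp: {
                        "total": rep.total,
                        "inconsistent": rep.inconsistent,
                        "counts": rep.counts(),
                    }
                    for hyp, rep in (
                        ("mora", consistency_score(contrasts, "mora")),
                        ("vowel-length",
                         consistency_score(contrasts, "vowel-length")),
                    )
                }
        return bundle

    stats_bundle = run_stats()

    @_stage("distinctiveness")
    def run_distinctiveness():
        if not lexicon:
            return None
        rep = homophone_classes(lexicon, position="final")
        summary = rep.summary()
        payload = {
            "summary": summary,
            "by_signature": {k: list(v) for k, v in rep.by_signature.items()},
        }
        (out / "homophones.json").write_text(
            json.dumps(payload, ensure_ascii=False, indent=2),
            encoding="utf-8",
        )
        return summary

    distinct = run_distinctiveness()

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.digest(),
        "n_observations": int(len(df)),
        "n_messages_aligned": len(corpus.messages) if corpus else None,
        "n_messages_slipped": len(corpus.slipped) if corpus else None,
    }
    report = {
        "provenance": provenance,
        "stats": stats_bundle,
        "distinctiveness": distinct,
    }
    (out / "report.json").write_text(
        json.dumps(report, ensure_ascii=False, indent=2, sort_keys=True),
        encoding="utf-8",
    )
    return report
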