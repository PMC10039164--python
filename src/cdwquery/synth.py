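"""Seeded synthetic hospital extract: clinical records plus DICOM metadata.

No real hospital extract can ship with the package, so this module
generates one with the structural features the multilevel queries
exploit:

* patients with multiple encounters, encounters with multiple radiology
  reports, each report with an accession-linked DICOM study of several
  series;
* a cardiac-MR sub-population of reports (order identifiers ``CMRA`` /
  ``CMRB``, study description mentioning "cardiac") whose studies hold
  MR acquisitions *plus* PR presentation-state series — the planted
  contaminant that a document-level join sweeps up;
* generic studies whose series modalities draw i.i.d. from a
  configurable mix (MR-dominated, with PR/XA/CT/US contaminants) — the
  material an encounter-level join sweeps up;
* a fraction of orphan series without accession numbers, exercising the
  Study-UID fallback document;
* a heart-failure phenotype bundle on a configurable fraction of
  encounters: a letter phrase discoverable by regex, a reduced LVEF
  value, an ICD code from {I11, I13, I50}, and an elevated NT-proBNP.

Everything is driven by one integer seed; the same config yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .clinical import (
    ClinicalIngestor,
    ClinicalObservation,
    EncounterRecord,
    RadiologyReport,
)
from .dicom import SeriesMetadata, ingest_series, write_series_table
from .store import EAVStore

__all__ = [
    "SyntheticConfig",
    "HospitalData",
    "generate_hospital",
    "build_store",
    "write_hospital",
    "load_hospital",
    "write_dicom_files",
    "worked_example_stemi",
    "worked_example_hf",
    "RADIOLOGY_QUERY",
    "DISEASE_QUERY",
    "STEMI_QUERY",
    "HF_QUERY",
    "HF_LETTER_MARKER",
]

#: private UID root used for all generated Study/Series Instance UIDs
UID_ROOT = "1.2.826.0.1.3680043.10.999"

#: the regex-discoverable heart-failure phrase planted in letters
HF_LETTER_MARKER = "dekompensierte Herzinsuffizienz"

#: the radiology-oriented query archetype: report conditions at document
#: level, modality refinement at group level
RADIOLOGY_QUERY = (
    'DOCUMENT: RadiologyOrder matches "CMR(A|B)"'
    ' OR StudyDescription contains "cardiac"\n'
    'GROUP: Modality == "MR"\n'
)

#: the disease-oriented query archetype: heart-failure phenotype at
#: encounter level, report existence at document level, MR at group level
DISEASE_QUERY = (
    f'ENCOUNTER: PhysicianLetter matches "{HF_LETTER_MARKER}"'
    ' AND LVEF < 45'
    ' AND (ICD == "I11" OR ICD == "I13" OR ICD == "I50")\n'
    'DOCUMENT: RadiologyOrder exists\n'
    'GROUP: Modality == "MR"\n'
)

#: same-specimen co-occurrence of two infarction markers
STEMI_QUERY = "DOCUMENT: TroponinT > 0.5 AND CK-MB > 25\n"

#: encounter-level heart-failure screen on two aggregated variables
HF_QUERY = 'ENCOUNTER: NT-proBNP > 1000 AND ICD matches "^I50"\n'


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the study conditions used
    throughout the test-suite and the acceptance run."""

    n_patients: int = 200
    #: mean encounters per patient (1 + Poisson(mean - 1))
    encounters_per_patient: float = 2.0
    #: mean radiology reports per encounter (Poisson)
    reports_per_encounter: float = 0.7
    #: mean DICOM series per study (1 + Poisson(mean - 1))
    series_per_study: float = 5.0
    #: probability that a series carries no accession number
    p_orphan_series: float = 0.15
    #: series modality mix of generic (non-cardiac) studies
    modality_mix: Mapping[str, float] = field(default_factory=lambda: {
        "MR": 0.50, "PR": 0.20, "XA": 0.12, "CT": 0.10, "US": 0.08,
    })
    #: fraction of reports that are cardiac-MR examinations
    p_cardiac_report: float = 0.3
    #: probability that a non-leading series of a cardiac study is a PR
    #: presentation state rather than an MR acquisition
    p_cardiac_pr: float = 0.25
    #: prevalence of the heart-failure phenotype bundle among encounters
    p_heart_failure: float = 0.2
    admission_window: tuple[_dt.date, _dt.date] = (
        _dt.date(2016, 1, 1), _dt.date(2017, 12, 31),
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.encounters_per_patient < 1:
            raise ValueError("encounters_per_patient must be >= 1")
        if self.series_per_study < 1:
            raise ValueError("series_per_study must be >= 1")
        for name in ("reports_per_encounter",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_orphan_series", "p_cardiac_report", "p_cardiac_pr",
                     "p_heart_failure"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        total = sum(self.modality_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"modality_mix sums to {total}, not 1")
        if self.admission_window[0] > self.admission_window[1]:
            raise ValueError("admission_window start after end")


@dataclass
class HospitalData:
    """One generated extract, ready for ingestion or file output."""

    encounters: list[EncounterRecord]
    reports: list[RadiologyReport]
    observations: list[ClinicalObservation]
    series: list[SeriesMetadata]
    config: SyntheticConfig


_GENERIC_ORDERS = ("XR10", "CT20", "US30", "XA40", "NM50")
_GENERIC_DESCRIPTIONS = (
    "Thorax examination", "Abdomen survey", "Angiography run",
    "Sonography upper abdomen", "Skeletal survey",
)
_OTHER_ICD = ("I10", "E11.9", "J18.9", "N18.3", "K29.7")
_FINDING_SNIPPETS = (
    "No acute abnormality.", "Findings consistent with prior examination.",
    "Mild degenerative changes.", "Follow-up recommended.",
    "Unremarkable study.",
)


def generate_hospital(config: SyntheticConfig = SyntheticConfig()) -> HospitalData:
    """Generate a synthetic extract; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    window_start, window_end = config.admission_window
    n_days = (window_end - window_start).days + 1

    modalities = sorted(config.modality_mix)
    mix = np.array([config.modality_mix[m] for m in modalities])
    mix = mix / mix.sum()

    encounters: list[EncounterRecord] = []
    reports: list[RadiologyReport] = []
    observations: list[ClinicalObservation] = []
    series_list: list[SeriesMetadata] = []
    enc_counter = report_counter = study_counter = series_counter = 0

    for p in range(1, config.n_patients + 1):
        patient_id = f"P{p:05d}"
        # patient-anchored demographics (no encounter/document/group)
        observations.append(ClinicalObservation(
            patient_id=patient_id, concept_id="Sex",
            value="F" if rng.random() < 0.5 else "M",
        ))
        observations.append(ClinicalObservation(
            patient_id=patient_id, concept_id="BirthYear",
            value=float(rng.integers(1930, 2000)),
        ))
        n_enc = 1 + int(rng.poisson(config.encounters_per_patient - 1))
        for _ in range(n_enc):
            enc_counter += 1
            encounter_id = f"E{enc_counter:06d}"
            admission = window_start + _dt.timedelta(
                days=int(rng.integers(0, n_days))
            )
            encounters.append(EncounterRecord(
                patient_id, encounter_id, admission, department="IM"
            ))

            hf = bool(rng.random() < config.p_heart_failure)
            observations.extend(_encounter_observations(
                rng, patient_id, encounter_id, admission, hf
            ))

            for _ in range(int(rng.poisson(config.reports_per_encounter))):
                report_counter += 1
                study_counter += 1
                cardiac = bool(rng.random() < config.p_cardiac_report)
                accession = f"ACC{report_counter:07d}"
                document_id = f"RPT{report_counter:06d}"
                if cardiac:
                    order = "CMRA" if rng.random() < 0.5 else "CMRB"
                    study_description = "Cardiac MRI examination"
                else:
                    order = _GENERIC_ORDERS[int(rng.integers(len(_GENERIC_ORDERS)))]
                    study_description = _GENERIC_DESCRIPTIONS[
                        int(rng.integers(len(_GENERIC_DESCRIPTIONS)))
                    ]
                reports.append(RadiologyReport(
                    accession_number=accession,
                    patient_id=patient_id,
                    encounter_id=encounter_id,
                    document_id=document_id,
                    order_identifier=order,
                    short_finding=_FINDING_SNIPPETS[
                        int(rng.integers(len(_FINDING_SNIPPETS)))
                    ],
                    finding=_FINDING_SNIPPETS[
                        int(rng.integers(len(_FINDING_SNIPPETS)))
                    ],
                    assessment=_FINDING_SNIPPETS[
                        int(rng.integers(len(_FINDING_SNIPPETS)))
                    ],
                    report_date=admission,
                ))

                study_uid = f"{UID_ROOT}.1.{study_counter}"
                n_series = 1 + int(rng.poisson(config.series_per_study - 1))
                for s in range(n_series):
                    series_counter += 1
                    if cardiac:
                        modality = ("MR" if s == 0
                                    or rng.random() >= config.p_cardiac_pr
                                    else "PR")
                        series_description = (
                            f"cine MR sequence {s + 1}" if modality == "MR"
                            else "presentation state"
                        )
                    else:
                        modality = modalities[
                            int(rng.choice(len(modalities), p=mix))
                        ]
                        series_description = f"series {s + 1}"
                    orphan = bool(rng.random() < config.p_orphan_series)
                    series_list.append(SeriesMetadata(
                        dicom_patient_id=patient_id,
                        accession_number=None if orphan else accession,
                        study_instance_uid=study_uid,
                        series_instance_uid=f"{UID_ROOT}.2.{series_counter}",
                        modality=modality,
                        study_description=study_description,
                        series_description=series_description,
                    ))
    return HospitalData(encounters, reports, observations, series_list, config)


def _encounter_observations(
    rng: np.random.Generator,
    patient_id: str,
    encounter_id: str,
    admission: _dt.date,
    hf: bool,
) -> list[ClinicalObservation]:
    def obs(concept: str, value: object) -> ClinicalObservation:
        return ClinicalObservation(
            patient_id=patient_id, encounter_id=encounter_id,
            concept_id=concept, value=value, observed_at=admission,
        )

    out: list[ClinicalObservation] = []
    if hf:
        out.append(obs(
            "PhysicianLetter",
            f"Stationaere Aufnahme bei {HF_LETTER_MARKER}. "
            "Echokardiographie mit reduzierter Pumpfunktion.",
        ))
        out.append(obs("LVEF", float(np.round(rng.uniform(20, 40), 1))))
        out.append(obs("ICD", ("I11", "I13", "I50")[int(rng.integers(3))]))
        out.append(obs("NT-proBNP", float(np.round(rng.uniform(1100, 8000), 0))))
    else:
        out.append(obs(
            "PhysicianLetter",
            "Stationaere Aufnahme zur weiteren Abklaerung. "
            "Verlauf unauffaellig, Entlassung in gutem Zustand.",
        ))
        if rng.random() < 0.3:
            out.append(obs("LVEF", float(np.round(rng.uniform(50, 70), 1))))
        if rng.random() < 0.8:
            out.append(obs("ICD", _OTHER_ICD[int(rng.integers(len(_OTHER_ICD)))]))
        if rng.random() < 0.4:
            out.append(obs("NT-proBNP", float(np.round(rng.uniform(50, 900), 0))))
    return out


def build_store(data: HospitalData, path: str = ":memory:") -> EAVStore:
    """Ingest a generated extract into a fresh store (clinical first,
    then DICOM series linked through the report index)."""
    store = EAVStore(path)
    ingestor = ClinicalIngestor(store)
    ingestor.ingest(
        encounters=data.encounters,
        reports=data.reports,
        observations=data.observations,
    )
    ingest_series(data.series, ingestor.index, store)
    store.commit()
    return store


# ----------------------------------------------------------------------
# file round-trip
# ----------------------------------------------------------------------

def write_hospital(data: HospitalData, outdir: str) -> None:
    """Write the extract in the ingestion CSV dialects plus a manifest
    recording config and seed; byte-identical for identical input."""
    os.makedirs(outdir, exist_ok=True)
    import csv

    with open(os.path.join(outdir, "encounters.csv"), "w", newline="",
              encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "encounter_id", "admission_date", "department"])
        for enc in data.encounters:
            writer.writerow([enc.patient_id, enc.encounter_id,
                             enc.admission_date.isoformat(), enc.department])

    with open(os.path.join(outdir, "reports.csv"), "w", newline="",
              encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession_number", "patient_id", "encounter_id",
                         "document_id", "order_identifier", "short_finding",
                         "finding", "assessment", "report_date"])
        for r in data.reports:
            writer.writerow([
                r.accession_number, r.patient_id, r.encounter_id, r.document_id,
                r.order_identifier, r.short_finding, r.finding, r.assessment,
                r.report_date.isoformat() if r.report_date else "",
            ])

    with open(os.path.join(outdir, "observations.csv"), "w", newline="",
              encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "encounter_id", "document_id", "group_id",
                         "concept_id", "value", "observed_at"])
        for o in data.observations:
            value = o.value
            if isinstance(value, float) and value.is_integer():
                value = int(value)
            writer.writerow([
                o.patient_id, o.encounter_id or "", o.document_id or "",
                o.group_id or "", o.concept_id, value,
                o.observed_at.isoformat() if o.observed_at else "",
            ])

    write_series_table(data.series, os.path.join(outdir, "series.csv"))

    manifest = dataclasses.asdict(data.config)
    manifest["modality_mix"] = dict(data.config.modality_mix)
    manifest["admission_window"] = [d.isoformat() for d in data.config.admission_window]
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_hospital(outdir: str) -> HospitalData:
    from .clinical import load_encounters, load_observations, load_reports
    from .dicom import read_series_metadata

    with open(os.path.join(outdir, "manifest.json"), encoding="utf-8") as fh:
        manifest = json.load(fh)
    manifest["modality_mix"] = dict(manifest["modality_mix"])
    manifest["admission_window"] = tuple(
        _dt.date.fromisoformat(d) for d in manifest["admission_window"]
    )
    config = SyntheticConfig(**manifest)
    return HospitalData(
        encounters=load_encounters(os.path.join(outdir, "encounters.csv")),
        reports=load_reports(os.path.join(outdir, "reports.csv")),
        observations=load_observations(os.path.join(outdir, "observations.csv")),
        series=list(read_series_metadata(os.path.join(outdir, "series.csv"))),
        config=config,
    )


def write_dicom_files(series: Sequence[SeriesMetadata], outdir: str) -> list[str]:
    """Emit one minimal DICOM Part-10 file per series (header only, no
    pixel data) for end-to-end testing of the file reader."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i, meta in enumerate(series, start=1):
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        file_meta.MediaStorageSOPInstanceUID = f"{meta.series_instance_uid}.{i}"
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = file_meta
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = f"{meta.series_instance_uid}.{i}"
        ds.PatientID = meta.dicom_patient_id
        if meta.accession_number:
            ds.AccessionNumber = meta.accession_number
        ds.StudyInstanceUID = meta.study_instance_uid
        ds.SeriesInstanceUID = meta.series_instance_uid
        ds.Modality = meta.modality
        ds.StudyDescription = meta.study_description
        ds.SeriesDescription = meta.series_description
        path = os.path.join(outdir, f"series{i:05d}.dcm")
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


# ----------------------------------------------------------------------
# worked-example fixtures
# ----------------------------------------------------------------------

def worked_example_stemi() -> EAVStore:
    """Two encounters with elevated troponin T and CK-MB: in one the two
    markers share a laboratory report (document), in the other they sit
    in two different reports.  Document-level co-occurrence selects only
    the first; an encounter-level join selects both.  No imaging rows."""
    store = EAVStore()
    ingestor = ClinicalIngestor(store)
    ingestor.ingest_encounter(EncounterRecord(
        "STEMI-P1", "E-SAME", _dt.date(2017, 3, 1), "IM"
    ))
    ingestor.ingest_encounter(EncounterRecord(
        "STEMI-P2", "E-SPLIT", _dt.date(2017, 3, 2), "IM"
    ))

    def lab(patient: str, encounter: str, document: str,
            concept: str, value: float) -> None:
        ingestor.ingest_observation(ClinicalObservation(
            patient_id=patient, encounter_id=encounter, document_id=document,
            concept_id=concept, value=value,
        ))

    # both markers elevated within one laboratory report
    lab("STEMI-P1", "E-SAME", "LAB-1", "TroponinT", 0.9)
    lab("STEMI-P1", "E-SAME", "LAB-1", "CK-MB", 30.0)
    # the same elevations, split over two reports of one encounter
    lab("STEMI-P2", "E-SPLIT", "LAB-2", "TroponinT", 0.8)
    lab("STEMI-P2", "E-SPLIT", "LAB-3", "CK-MB", 40.0)
    return store


def worked_example_hf() -> EAVStore:
    """Three encounters: both heart-failure markers, only the elevated
    NT-proBNP, only the ICD code.  The AND query selects exactly the
    first; swapping AND for OR selects all three."""
    store = EAVStore()
    ingestor = ClinicalIngestor(store)

    def enc(patient: str, encounter: str, day: int) -> None:
        ingestor.ingest_encounter(EncounterRecord(
            patient, encounter, _dt.date(2016, 6, day), "IM"
        ))

    def obs(patient: str, encounter: str, concept: str, value: object) -> None:
        ingestor.ingest_observation(ClinicalObservation(
            patient_id=patient, encounter_id=encounter,
            concept_id=concept, value=value,
        ))

    enc("HF-P1", "E-BOTH", 1)
    obs("HF-P1", "E-BOTH", "NT-proBNP", 2500.0)
    obs("HF-P1", "E-BOTH", "ICD", "I50")
    enc("HF-P2", "E-BNP", 2)
    obs("HF-P2", "E-BNP", "NT-proBNP", 1800.0)
    enc("HF-P3", "E-ICD", 3)
    obs("HF-P3", "E-ICD", "ICD", "I50")
    return store
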