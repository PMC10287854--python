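"""DICOMweb URL grammar and FHIR/UPS mapping."""

from __future__ import annotations

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svgfhir import (
    CodingStub,
    DicomImageRef,
    EncounterResource,
    FhirReference,
    ServiceRequestResource,
    build_qido_query,
    build_wado_url,
    order_to_ups,
    parse_wado_url,
    study_to_imagingstudy,
    validate_resource,
)
from svgfhir.errors import (
    InconsistentOrderError,
    UnsupportedAttributeError,
    UrlFormatError,
)
from svgfhir.fixtures import gen_study

from conftest import image_refs


class TestWadoUrls:
    def test_instance_url_grammar(self):
        url = build_wado_url("https://s/dicomweb",
                             DicomImageRef("1.2.3", "1.2.3.4", "1.2.3.4.5"))
        assert url == ("https://s/dicomweb/studies/1.2.3/series/1.2.3.4"
                       "/instances/1.2.3.4.5")

    def test_frame_suffix(self):
        url = build_wado_url("https://s/dicomweb",
                             DicomImageRef("1.2", "1.3", "1.4", frame=7))
        assert url.endswith("/instances/1.4/frames/7")

    def test_trailing_slash_normalized(self):
        ref = DicomImageRef("1.2", "1.3", "1.4")
        assert build_wado_url("https://s/dicomweb/", ref) == \
            build_wado_url("https://s/dicomweb", ref)

    def test_study_level_url_rejected(self):
        with pytest.raises(UrlFormatError):
            parse_wado_url("https://s/dicomweb/studies/1.2.3")

    def test_series_level_url_rejected(self):
        with pytest.raises(UrlFormatError):
            parse_wado_url("https://s/dicomweb/studies/1.2.3/series/1.2.3.4")

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(image_refs)
    def test_build_parse_inverse(self, ref):
        base = "https://pacs.example.org/dicomweb"
        assert parse_wado_url(build_wado_url(base, ref)) == (base, ref)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(image_refs)
    def test_urls_are_ascii(self, ref):
        build_wado_url("https://s/dicomweb", ref).encode("ascii")


class TestQidoQueries:
    def test_single_filter(self):
        assert build_qido_query("https://s/dicomweb", "studies",
                                {"PatientID": "P1"}) == \
            "https://s/dicomweb/studies?PatientID=P1"

    def test_keys_sorted_deterministically(self):
        url = build_qido_query("https://s/dicomweb", "studies",
                               {"StudyInstanceUID": "1.2", "Modality": "CT"})
        assert url.endswith("?Modality=CT&StudyInstanceUID=1.2")

    def test_empty_filters_no_query(self):
        assert build_qido_query("https://s/dicomweb", "series", {}) == \
            "https://s/dicomweb/series"

    def test_values_percent_encoded(self):
        url = build_qido_query("https://s/dicomweb", "studies",
                               {"AccessionNumber": "A 1&2"})
        assert url.endswith("?AccessionNumber=A%201%262")

    def test_unknown_attribute_rejected(self):
        with pytest.raises(UnsupportedAttributeError, match="PatientName"):
            build_qido_query("https://s/dicomweb", "studies",
                             {"PatientName": "Doe"})

    def test_whitelist_extensible(self):
        url = build_qido_query("https://s/dicomweb", "studies",
                               {"PatientName": "Doe"},
                               extra_attributes=frozenset({"PatientName"}))
        assert url.endswith("?PatientName=Doe")


class TestStudyMapping:
    def test_counts_from_record(self):
        study = gen_study(1, n_series=2, instances_per_series=3)
        study.series[1].instance_uids.append("2.25.999")  # 2 series: 3 + 4
        res = study_to_imagingstudy(study, "https://s/dicomweb")
        assert res.numberOfSeries == 2
        assert res.numberOfInstances == 7
        assert res.study_uid == study.study_uid
        assert res.endpoint == "https://s/dicomweb"

    def test_minimal_study(self):
        study = gen_study(2, n_series=1, instances_per_series=1)
        res = study_to_imagingstudy(study, "https://s/dicomweb")
        assert (res.numberOfSeries, res.numberOfInstances) == (1, 1)

    def test_series_order_and_modality_preserved(self):
        study = gen_study(3, n_series=4, instances_per_series=2)
        res = study_to_imagingstudy(study, "https://s/dicomweb")
        assert [s.series_uid for s in res.series] == \
            [s.series_uid for s in study.series]
        assert [s.modality for s in res.series] == \
            [s.modality for s in study.series]

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 4), st.integers(1, 5))
    def test_mapped_resource_always_valid(self, seed, n_series, n_inst):
        study = gen_study(seed, n_series=n_series,
                          instances_per_series=n_inst)
        res = study_to_imagingstudy(study, "https://s/dicomweb")
        assert validate_resource(res) == []
        assert res.numberOfInstances == n_series * n_inst


class TestOrderMapping:
    def _pair(self, subject_sr="Patient/P1", subject_enc="Patient/P1",
              planned="2021-01-01T09:00:00Z"):
        sr = ServiceRequestResource(
            id="sr-1", status="active", intent="order",
            code=CodingStub("urn:x", "CT-HEAD", "CT head"),
            subject=FhirReference(subject_sr), identifier="A001")
        enc = EncounterResource(
            id="enc-1", status="planned",
            subject=FhirReference(subject_enc),
            basedOn=FhirReference("ServiceRequest/sr-1"),
            planned_start=planned)
        return sr, enc

    def test_field_mapping(self):
        item = order_to_ups(*self._pair())
        assert item.state == "SCHEDULED"
        assert item.accession == "A001"
        assert item.scheduled_datetime == "2021-01-01T09:00:00Z"
        assert item.patient_ref == "Patient/P1"
        assert item.procedure_code.code == "CT-HEAD"
        assert item.input_order_id == "sr-1"

    def test_missing_planned_start(self):
        item = order_to_ups(*self._pair(planned=None))
        assert item.scheduled_datetime is None

    def test_subject_mismatch_rejected(self):
        with pytest.raises(InconsistentOrderError):
            order_to_ups(*self._pair(subject_enc="Patient/P2"))

    def test_json_uses_dicom_keywords(self):
        payload = json.loads(order_to_ups(*self._pair()).to_json())
        assert payload["ProcedureStepState"] == "SCHEDULED"
        assert payload["AccessionNumber"] == "A001"
        assert payload["ScheduledWorkitemCodeSequence"][0]["CodeValue"] == \
            "CT-HEAD"
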