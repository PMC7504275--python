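"""Relative retention time math, the identification chart, peak matching."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgoil.core import parse_tg_name
from tgoil.retention import (
    DegenerateReferenceError,
    ModelUnderdeterminedError,
    Peak,
    PeakTable,
    UnpredictableTGError,
    fit_identification_plot,
    identify_peaks,
    predict_rrt,
    read_model,
    relative_retention_time,
    resolve_reference_rrts,
    write_model,
)

# printed anchor rrts of the monoacid standards
ANCHORS = {"PPP": 0.70, "SSS": 0.91, "OOO": 0.93, "LLL": 0.97, "NNN": 1.00}


def _fit(rrts=None, **kw):
    rrts = rrts if rrts is not None else ANCHORS
    return fit_identification_plot(
        [(parse_tg_name(n), r) for n, r in rrts.items()], **kw
    )


class TestRrt:
    @pytest.mark.parametrize(
        "rt, expected", [(27.0, 1.0), (2.0, 0.0), (22.0, 0.80)]
    )
    def test_normalisation(self, rt, expected):
        assert relative_retention_time(rt, 2.0, 27.0) == pytest.approx(expected)

    def test_degenerate_reference(self):
        with pytest.raises(DegenerateReferenceError):
            relative_retention_time(5.0, 10.0, 10.0)

    @given(
        rt=st.floats(2.0, 27.0),
        shift=st.floats(-1.0, 100.0),
        stretch=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_affine_invariance(self, rt, shift, stretch):
        """rrt is unchanged by rescaling/shifting the clock of the whole run."""
        base = relative_retention_time(rt, 2.0, 27.0)
        moved = relative_retention_time(
            rt * stretch + shift, 2.0 * stretch + shift, 27.0 * stretch + shift
        )
        assert moved == pytest.approx(base, abs=1e-9)


class TestChart:
    def test_monoacid_anchor_passthrough(self, ref_model):
        for name, rrt in ANCHORS.items():
            assert predict_rrt(ref_model, parse_tg_name(name)) == pytest.approx(rrt)

    @pytest.mark.parametrize(
        "name, closed_form",
        [
            # two-acyl TGs: interpolation on the (DB, log rrt) segment, which
            # equals mole-fraction weighting of the two anchor log-rrts
            ("OOL", 0.93 ** (2 / 3) * 0.97 ** (1 / 3)),
            ("LLO", 0.93 ** (1 / 3) * 0.97 ** (2 / 3)),
            ("OOS", 0.91 ** (1 / 3) * 0.93 ** (2 / 3)),
            ("OOP", 0.70 ** (1 / 3) * 0.93 ** (2 / 3)),
            ("LLS", 0.91 ** (1 / 3) * 0.97 ** (2 / 3)),
            # both anchors saturated (DB 0): mole-fraction limit
            ("PPS", (0.70 ** 2 * 0.91) ** (1 / 3)),
            # three distinct acyls: mean of the two non-degenerate pairwise
            # lines (P/O and S/O) evaluated at DB = 1
            ("PSO", math.sqrt((0.70 ** (2 / 3) * 0.93 ** (1 / 3))
                              * (0.91 ** (2 / 3) * 0.93 ** (1 / 3)))),
        ],
    )
    def test_predictions_match_closed_form(self, ref_model, name, closed_form):
        assert predict_rrt(ref_model, parse_tg_name(name)) == pytest.approx(
            closed_form, abs=1e-12
        )

    def test_mixed_standards_predicted_within_002(self, ref_model, standards):
        """Chart predictions reproduce the measured rrt of every mixed-acid
        standard built from anchored acyls to within 0.02."""
        printed = dict(zip(standards["tg"], standards["rrt"]))
        for name in ("OOL", "OOP", "OPO", "LLO", "LOL", "LLS", "OOS", "PSO", "PPS",
                     "PPL", "SSO"):
            pred = predict_rrt(ref_model, parse_tg_name(name))
            assert abs(pred - printed[name]) <= 0.02, name

    def test_underdetermined_chart(self):
        with pytest.raises(ModelUnderdeterminedError):
            _fit({"OOO": 0.93})
        # two anchors at the same DB define no line either
        with pytest.raises(ModelUnderdeterminedError):
            _fit({"PPP": 0.70, "SSS": 0.91})

    def test_virtual_anchor_for_acyl_without_monoacid_standard(self):
        """OOLn pins a virtual linolenoyl anchor; without inference the TG is
        unpredictable."""
        rrts = dict(ANCHORS, OOLn=0.96)
        model = fit_identification_plot(
            [(parse_tg_name(n), r) for n, r in rrts.items()]
        )
        assert model.anchors["Ln"].virtual
        # solving the O/Ln line through OOLn (DB 5) for the DB 9 endpoint
        assert model.anchors["Ln"].rrt == pytest.approx(
            0.93 * (0.96 / 0.93) ** 3, abs=1e-12
        )
        assert predict_rrt(model, parse_tg_name("OOLn")) == pytest.approx(0.96)

        bare = fit_identification_plot(
            [(parse_tg_name(n), r) for n, r in rrts.items()],
            infer_missing_anchors=False,
        )
        with pytest.raises(UnpredictableTGError):
            predict_rrt(bare, parse_tg_name("OOLn"))

    def test_model_file_round_trip(self, ref_model, tmp_path):
        path = tmp_path / "model.txt"
        write_model(ref_model, path)
        back = read_model(path)
        assert back.tolerance == ref_model.tolerance
        assert back.anchors == ref_model.anchors


def _table(rrts, solvent_rt=2.0, is_rt=27.0, area=1000.0):
    peaks = [
        Peak(rt=solvent_rt, area=5e6, role="solvent"),
        Peak(rt=is_rt, area=1e6, role="is"),
    ] + [Peak(rt=solvent_rt + r * (is_rt - solvent_rt), area=area) for r in rrts]
    return PeakTable(peaks=peaks, solvent_rt=solvent_rt, is_rt=is_rt)


class TestIdentify:
    def test_unique_match(self, ref_model, standards):
        matches = identify_peaks(_table([0.70]), ref_model, standards["tg"])
        assert [m.best for m in matches] == ["PPP"]
        assert [name for name, _, _ in matches[0].candidates] == ["PPP"]

    def test_ambiguous_match_reports_full_ranked_set(self, ref_model, standards):
        """A peak at rrt 0.85 is consistent with both OOP and PSO."""
        (m,) = identify_peaks(_table([0.85]), ref_model, standards["tg"])
        names = [name for name, _, _ in m.candidates]
        assert set(names) == {"OOP", "PSO"}
        assert m.best == "OOP"  # closer prediction ranks first

    def test_positional_isomers_collapse(self, ref_model):
        (m,) = identify_peaks(_table([0.85]), ref_model, ["OOP", "OPO"])
        assert [name for name, _, _ in m.candidates] == ["OOP"]

    def test_rrt_not_strictly_monotone_in_db(self, ref_model, standards):
        """SSO and SSS share printed rrt 0.91; matching tolerates the tie."""
        (m,) = identify_peaks(_table([0.91]), ref_model, standards["tg"])
        assert {name for name, _, _ in m.candidates} >= {"SSO", "SSS"}

    def test_unknown_peak_and_empty_table(self, ref_model, standards):
        (m,) = identify_peaks(_table([0.50]), ref_model, standards["tg"])
        assert m.is_unknown and m.best is None
        assert identify_peaks(_table([]), ref_model, standards["tg"]) == []

    def test_area_floor_drops_trace_peaks(self, ref_model, standards):
        table = _table([0.70, 0.93])
        table.analytes[0].area = 1.0
        matches = identify_peaks(table, ref_model, standards["tg"], area_floor=10.0)
        assert [m.best for m in matches] == ["OOO"]

    def test_reference_rrt_matching_separates_grid_collisions(
        self, ref_model, standards
    ):
        refs = resolve_reference_rrts(
            dict(zip(standards["tg"], standards["rrt"])), ref_model
        )
        # de-rounded references are distinct and round back to the grid value
        assert refs["OOP"] != refs["PSO"]
        assert round(refs["OOP"], 2) == round(refs["PSO"], 2) == 0.85
        # positional isomers keep identical positions
        assert refs["LLO"] == refs["LOL"]
        for rrt, best in ((refs["OOP"], "OOP"), (refs["PSO"], "PSO")):
            (m,) = identify_peaks(
                _table([rrt]), ref_model, standards["tg"], reference_rrt=refs
            )
            assert m.best == best


class TestPeakTableInvariants:
    def test_peak_validation(self):
        with pytest.raises(ValueError):
            Peak(rt=-1.0, area=10.0)
        with pytest.raises(ValueError):
            Peak(rt=1.0, area=-10.0)

    def test_solvent_before_is(self):
        with pytest.raises(DegenerateReferenceError):
            PeakTable(peaks=[], solvent_rt=27.0, is_rt=2.0)

    def test_peaks_sorted_by_rt(self):
        table = _table([0.9, 0.3, 0.6])
        assert [p.rt for p in table.peaks] == sorted(p.rt for p in table.peaks)
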