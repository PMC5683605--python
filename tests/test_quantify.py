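"""Peak-set detection, identification validation and censored ratios."""

import numpy as np
import pytest

from cpdpep.constants import TMAB_CHANNELS
from cpdpep.peptide_chem import Peptide, monoisotopic_mass, parse_peptide
from cpdpep.quantify import (
    PeakList,
    compute_ratios,
    detect_peaksets,
    read_peaklist,
    select_major_fragments,
    validate_identification,
    write_peaklist,
)
from cpdpep.tmab import peakset_pattern

CHANNEL_CONDITION = {
    "D0": "100nM",
    "D3": "10nM",
    "D6": "1nM",
    "D9": "0.1nM",
    "D12": "0nM",
}


def make_peaklist(patterns_with_intensities, extra=()):
    """Build a sorted PeakList from (pattern, per-channel intensity) pairs."""
    mz, inten = [], []
    for pattern, intensities in patterns_with_intensities:
        for ch in TMAB_CHANNELS:
            if intensities.get(ch, 0.0) > 0:
                mz.append(pattern.channel_mz[ch])
                inten.append(intensities[ch])
    for m, i in extra:
        mz.append(m)
        inten.append(i)
    order = np.argsort(mz)
    return PeakList(
        run_id="test",
        mz=tuple(float(mz[i]) for i in order),
        intensity=tuple(float(inten[i]) for i in order),
    )


class TestDetection:
    def test_ideal_pattern_recovered_exactly_once(self):
        p = Peptide("QQAAALAK")
        pattern = peakset_pattern(p, 2)
        intensities = {ch: 1000.0 for ch in TMAB_CHANNELS}
        peaks = make_peaklist([(pattern, intensities)])
        found = detect_peaksets(peaks, [p])
        assert len(found) == 1
        ps = found[0]
        assert ps.n_matched == 5
        assert all(abs(v) < 1e-9 for v in ps.match_ppm.values())
        assert ps.channel_intensity == intensities

    def test_missing_channel_reported_as_zero(self):
        p = Peptide("QQAAALAK")
        pattern = peakset_pattern(p, 2)
        intensities = {ch: 500.0 for ch in TMAB_CHANNELS}
        intensities["D0"] = 0.0
        peaks = make_peaklist([(pattern, intensities)])
        ps = detect_peaksets(peaks, [p])[0]
        assert ps.channel_intensity["D0"] == 0.0
        assert ps.n_matched == 4

    def test_absent_peptide_not_reported(self):
        p = Peptide("QQAAALAK")
        other = Peptide("LVNELTEFAK")
        pattern = peakset_pattern(p, 2)
        peaks = make_peaklist([(pattern, {ch: 100.0 for ch in TMAB_CHANNELS})])
        assert detect_peaksets(peaks, [other]) == []

    def test_unsorted_peaklist_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            PeakList(run_id="x", mz=(500.0, 400.0), intensity=(1.0, 1.0))

    def test_many_injected_patterns_all_unique(self):
        rng = np.random.default_rng(0)
        peptides = []
        seen = set()
        while len(peptides) < 30:
            seq = "".join(rng.choice(list("ACDEFGLMNQSTV"), size=8)) + "K"
            if seq in seen:
                continue
            seen.add(seq)
            peptides.append(Peptide(seq))
        pairs = [
            (peakset_pattern(p, 2), {ch: 100.0 for ch in TMAB_CHANNELS})
            for p in peptides
        ]
        peaks = make_peaklist(pairs)
        found = detect_peaksets(peaks, peptides)
        assert len(found) == len(peptides)
        assert len({ps.pattern.base_peptide.sequence for ps in found}) == len(peptides)


class TestValidation:
    def test_mass_gate_at_50_ppm(self):
        p = Peptide("VDPVNFK")
        theor = monoisotopic_mass(p).monoisotopic_mass
        ok = validate_identification(p, 817.42, 2, 2)
        assert ok.mass_ok and abs(ok.ppm_error) < 50
        off = validate_identification(p, theor * (1 + 51e-6), 2, 2)
        assert not off.mass_ok

    def test_charge_admissibility(self):
        p = Peptide("KFEKLPESK")  # expected charge 4 (3K + N-terminus)
        assert validate_identification(p, 1104.62, 2, 4).charge_ok
        assert not validate_identification(p, 1104.62, 5, 4).charge_ok
        assert not validate_identification(
            p, 1104.62, 2, 4, strict_charge=True
        ).charge_ok

    def test_tag_count_gate(self):
        p = Peptide("KFEKLPESK")
        assert validate_identification(p, 1104.62, 2, 4).tag_ok
        assert not validate_identification(p, 1104.62, 2, 3).tag_ok

    def test_fragment_rule_minimum_five_matches(self):
        from cpdpep.peptide_chem import by_fragment_series

        p = Peptide("QQAAALAK")
        frags = [mz for _, mz in by_fragment_series(p)]
        # 4 of 5 submitted match (80%) but the count is below five
        rep = validate_identification(p, 799.46, 2, 2, ms2_fragments=frags[:4] + [1.0])
        assert rep.fragment_match_count == 4
        assert not rep.fragment_ok
        # 5 of 6 matches is >=80% with count >= 5
        rep = validate_identification(p, 799.46, 2, 2, ms2_fragments=frags[:5] + [1.0])
        assert rep.fragment_ok

    def test_no_ms2_leaves_fragments_unevaluated(self):
        rep = validate_identification(Peptide("QQAAALAK"), 799.46, 2, 2)
        assert rep.fragment_ok is None
        assert rep.accepted

    def test_excluded_residue_flag(self):
        rep = validate_identification(Peptide("ACDK"), 462.17, 2, 2)
        assert rep.excluded_residue_flag

    def test_major_fragment_selection(self):
        mzs = list(range(30))
        intens = [float(i) for i in range(30)]
        major = select_major_fragments(mzs, intens, top_n=20, rel_threshold=0.05)
        # top 20 plus anything >= 5% of the base peak (intensity >= 1.45)
        assert len(major) == 28
        assert select_major_fragments(mzs) == mzs


class TestRatios:
    def _peakset(self, intensities):
        p = Peptide("QQAAALAK")
        pattern = peakset_pattern(p, 2)
        peaks = make_peaklist([(pattern, intensities)])
        return detect_peaksets(peaks, [p])[0]

    def test_equal_channels_give_unit_ratios(self):
        ps = self._peakset({ch: 700.0 for ch in TMAB_CHANNELS})
        rp = compute_ratios(ps, CHANNEL_CONDITION, "0nM")
        assert all(r.value == pytest.approx(1.0) for r in rp.ratios.values())
        assert not any(r.censored for r in rp.ratios.values())

    def test_floor_censoring(self):
        ps = self._peakset(
            {"D0": 80.0, "D3": 900.0, "D6": 1000.0, "D9": 1000.0, "D12": 1000.0}
        )
        rp = compute_ratios(ps, CHANNEL_CONDITION, "0nM")
        assert rp.ratios["100nM"].value == 0.10
        assert rp.ratios["100nM"].censor == "low"

    def test_cap_censoring(self):
        ps = self._peakset(
            {"D0": 6000.0, "D3": 1000.0, "D6": 1000.0, "D9": 1000.0, "D12": 1000.0}
        )
        rp = compute_ratios(ps, CHANNEL_CONDITION, "0nM")
        assert rp.ratios["100nM"].value == 5.00
        assert rp.ratios["100nM"].censor == "high"

    def test_scale_invariance(self):
        base = {"D0": 100.0, "D3": 400.0, "D6": 800.0, "D9": 950.0, "D12": 1000.0}
        rp1 = compute_ratios(self._peakset(base), CHANNEL_CONDITION, "0nM")
        scaled = {ch: v * 37.5 for ch, v in base.items()}
        rp2 = compute_ratios(self._peakset(scaled), CHANNEL_CONDITION, "0nM")
        for cond in rp1.ratios:
            assert rp1.ratios[cond].value == pytest.approx(rp2.ratios[cond].value)

    def test_censoring_monotone_in_enzyme_intensity(self):
        """Lowering an enzyme-channel intensity never raises its ratio."""
        last = None
        for d0 in (1000.0, 500.0, 120.0, 90.0, 10.0):
            intens = {"D0": d0, "D3": 1000.0, "D6": 1000.0, "D9": 1000.0, "D12": 1000.0}
            rp = compute_ratios(self._peakset(intens), CHANNEL_CONDITION, "0nM",
                                background=50.0)
            r = rp.ratios["100nM"].value
            if last is not None:
                assert r <= last + 1e-12
            last = r

    def test_dead_control_is_unquantifiable(self):
        intens = {"D0": 500.0, "D3": 500.0, "D6": 500.0, "D9": 500.0, "D12": 0.0}
        rp = compute_ratios(self._peakset(intens), CHANNEL_CONDITION, "0nM")
        assert not rp.quantifiable


class TestIO:
    def test_peaklist_roundtrip(self, tmp_path):
        pl = PeakList(run_id="runA", mz=(400.1, 500.2), intensity=(10.0, 20.0))
        path = tmp_path / "peaks.tsv"
        write_peaklist(pl, path)
        back = read_peaklist(path)
        assert back.run_id == "runA"
        assert back.mz == pytest.approx(pl.mz)
        assert back.intensity == pytest.approx(pl.intensity)
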