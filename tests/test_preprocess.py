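import numpy as np
import pytest

from scmirna import preprocess as pp
from scmirna import simulate as sim
from scmirna.preprocess import TrimConfig, TrimStatus

from conftest import make_read

ADAPTER = sim.DEFAULT_ADAPTER3


def levenshtein(x, y):
    dp = list(range(len(y) + 1))
    for i in range(1, len(x) + 1):
        prev, dp[0] = dp[0], i
        for j in range(1, len(y) + 1):
            cur = dp[j]
            dp[j] = min(prev + (x[i - 1] != y[j - 1]), dp[j - 1] + 1, dp[j] + 1)
            prev = cur
    return dp[-1]


def adapter_oracle(seq, adapter, rate, min_prefix=3):
    """Exhaustive reference for find_adapter: for every start position,
    run a plain anchored edit-distance DP of the adapter against the read
    suffix; every (start, end) substring vs the full adapter and every
    terminal adapter prefix becomes a candidate, accepted on the
    error-rate rule and ordered by (errors, start)."""
    n, m = len(seq), len(adapter)
    acceptable = []
    for s in range(n):
        tail = seq[s:]
        # D[i][j] = lev(adapter[:i], tail[:j]), anchored at both starts
        D = [[0] * (len(tail) + 1) for _ in range(m + 1)]
        for i in range(m + 1):
            D[i][0] = i
        for j in range(len(tail) + 1):
            D[0][j] = j
        for i in range(1, m + 1):
            for j in range(1, len(tail) + 1):
                D[i][j] = min(
                    D[i - 1][j - 1] + (adapter[i - 1] != tail[j - 1]),
                    D[i - 1][j] + 1,
                    D[i][j - 1] + 1,
                )
        for j in range(len(tail) + 1):  # full adapter vs seq[s:s+j]
            if D[m][j] <= rate * m + 1e-9:
                acceptable.append((D[m][j], s))
        for k in range(min_prefix, m + 1):  # prefix k anchored at read end
            if D[k][len(tail)] <= rate * k + 1e-9:
                acceptable.append((D[k][len(tail)], s))
    return min(acceptable) if acceptable else None


def _substitute(seq, positions):
    repl = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for p in positions:
        out[p] = repl[out[p]]
    return "".join(out)


def quality_oracle(quals, cutoff):
    """Brute force over all cut positions: minimise the suffix sum of
    (q - cutoff); ties keep the longest read."""
    n = len(quals)
    best_cut, best_sum = n, 0
    for cut in range(n, -1, -1):
        s = sum(q - cutoff for q in quals[cut:])
        if s < best_sum:
            best_cut, best_sum = cut, s
    return best_cut


class TestExtractUmi:
    def test_first_bases_become_umi(self):
        read = make_read("AACCGGTTACGTACGTACGTACGT")
        out = pp.extract_umi(read, 8)
        assert out.umi == "AACCGGTT"
        assert out.sequence == "ACGTACGTACGTACGT"
        assert len(out.qualities) == len(out.sequence)

    def test_zero_length_is_identity(self):
        read = make_read("ACGT")
        assert pp.extract_umi(read, 0) is read

    def test_n_in_umi_is_flagged_verbatim(self):
        read = make_read("AANCGGTTACGTACGTACGT")
        out = pp.extract_umi(read, 8)
        assert out.umi == "AANCGGTT"
        assert "umi_has_n" in out.flags

    def test_read_shorter_than_umi_flagged(self):
        out = pp.extract_umi(make_read("ACG"), 8)
        assert "umi_truncated" in out.flags
        assert out.sequence == ""


class TestQualityTrim:
    def test_all_high_quality_unchanged(self):
        read = make_read("ACGTACGT", quals=[40] * 8)
        assert pp.quality_trim_3prime(read, 20) is read

    def test_all_low_quality_empties_read(self):
        read = make_read("ACGT", quals=[2] * 4)
        assert pp.quality_trim_3prime(read, 20).sequence == ""

    def test_partial_sum_rule_example(self):
        read = make_read("ACGTA", quals=[40, 40, 40, 2, 2])
        out = pp.quality_trim_3prime(read, 20)
        assert out.sequence == "ACG"  # cut minimising suffix sum (oracle-derived)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            n = int(rng.integers(1, 30))
            quals = rng.integers(2, 41, size=n).tolist()
            read = make_read("A" * n, quals=quals)
            out = pp.quality_trim_3prime(read, 20)
            assert len(out) == quality_oracle(quals, 20)


class TestFindAdapter:
    def test_exact_adapter_after_insert(self):
        seq = "A" * 22 + ADAPTER
        m = pp.find_adapter(seq, ADAPTER, 0.10)
        assert (m.start, m.errors) == (22, 0)

    def test_two_substitutions_in_20mer_accepted(self):
        adapter = ADAPTER[:20]  # 20 nt, 10% rate -> 2 errors allowed
        body = _substitute(adapter, [2, 11])
        seq = "CCACCACCAC" + body + "CACA"
        m = pp.find_adapter(seq, adapter, 0.10)
        assert m is not None and m.errors == 2  # 2/20 = 10%

    def test_three_substitutions_in_20mer_rejected(self):
        adapter = ADAPTER[:20]
        body = _substitute(adapter, [2, 11, 17])
        seq = "CCACCACCAC" + body + "CACA"
        assert pp.find_adapter(seq, adapter, 0.10) is None  # 3/20 = 15%

    def test_terminal_prefix_min_three(self):
        seq = "ACGTACGTACGTACGTAC" + ADAPTER[:3]
        m = pp.find_adapter(seq, ADAPTER, 0.10)
        assert (m.start, m.matched_len) == (18, 3)

    def test_absent_adapter_returns_none(self):
        assert pp.find_adapter("A" * 30, "CTCTCTCTCTCT", 0.10) is None

    def test_empty_adapter_raises(self):
        with pytest.raises(ValueError):
            pp.find_adapter("ACGT", "", 0.10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(1, 41))
            seq = "".join(rng.choice(list("ACGT"), n))
            m = int(rng.integers(3, 22))
            adapter = "".join(rng.choice(list("ACGT"), m))
            if rng.random() < 0.6 and n > 5:  # plant a mutated copy
                pos = int(rng.integers(0, n))
                sl = list(seq)
                for i, c in enumerate(adapter):
                    if pos + i < n and rng.random() > 0.12:
                        sl[pos + i] = c
                seq = "".join(sl)
            rate = float(rng.choice([0.1, 0.15, 0.2]))
            got = pp.find_adapter(seq, adapter, rate)
            exp = adapter_oracle(seq, adapter, rate)
            assert (None if got is None else (got.errors, got.start)) == exp


class TestTrimRead:
    def test_adapter_only_read_is_dimer(self, trim_cfg):
        read = make_read(ADAPTER + "G" * 20)
        out = pp.trim_read(read, trim_cfg)
        assert out.status is TrimStatus.ADAPTER_DIMER

    def test_22nt_insert_kept(self, trim_cfg):
        insert = "ACGTACGTACGTACGTACGTAC"
        out = pp.trim_read(make_read(insert + ADAPTER + "GGGG"), trim_cfg)
        assert out.status is TrimStatus.KEPT
        assert out.trimmed.sequence == insert

    def test_16nt_insert_too_short(self, trim_cfg):
        insert = "ACGTACGTACGTACGT"
        out = pp.trim_read(make_read(insert + ADAPTER), trim_cfg)
        assert out.status is TrimStatus.TOO_SHORT

    def test_three_n_bases_fail_quality(self, trim_cfg):
        insert = "ANGTANGTACGTANGTACGTAC"
        out = pp.trim_read(make_read(insert + ADAPTER), trim_cfg)
        assert out.status is TrimStatus.QUALITY_FAIL

    def test_two_n_bases_kept(self, trim_cfg):
        insert = "ANGTANGTACGTACGTACGTAC"
        out = pp.trim_read(make_read(insert + ADAPTER), trim_cfg)
        assert out.status is TrimStatus.KEPT

    def test_dimer_precedence_over_quality(self, trim_cfg):
        # a 2-nt N-containing remnant is a dimer, not a quality failure
        out = pp.trim_read(make_read("NN" + ADAPTER), trim_cfg)
        assert out.status is TrimStatus.ADAPTER_DIMER

    def test_polya_tail_removed(self, trim_cfg):
        insert = "CGTACGTACGTCCGTACGTACG"
        out = pp.trim_read(make_read(insert + "A" * 14), trim_cfg)
        assert out.status is TrimStatus.KEPT
        assert out.trimmed.sequence == insert

    def test_quality_then_adapter(self, trim_cfg):
        insert = "ACGTACGTACGTACGTACGTAC"
        seq = insert + ADAPTER + "GGGGG"
        quals = [40] * (len(seq) - 10) + [2] * 10  # tail dips into the pad
        out = pp.trim_read(make_read(seq, quals=quals), trim_cfg)
        assert out.status is TrimStatus.KEPT
        assert out.trimmed.sequence == insert

    def test_4n_flanks_clipped(self):
        cfg = TrimConfig(flank4n_len=4)
        insert = "ACGTACGTACGTACGTACGTAC"
        read = make_read("TTTT" + insert + "CCCC" + ADAPTER + "GG")
        out = pp.trim_read(read, cfg)
        assert out.status is TrimStatus.KEPT
        assert out.trimmed.sequence == insert

    def test_kept_output_is_idempotent(self, refs_small, arch, trim_cfg):
        lib = sim.simulate_library(
            refs_small, arch, sim.LibrarySimConfig(n_reads=400, seed=3)
        )
        kept, _ = pp.preprocess_reads(lib.reads, trim_cfg, umi_len=arch.umi_len)
        for rec in kept[:150]:
            again = pp.trim_read(rec, trim_cfg)
            assert again.status is TrimStatus.KEPT
            assert again.trimmed.sequence == rec.sequence

    def test_status_partition(self, refs_small, arch, trim_cfg):
        lib = sim.simulate_library(
            refs_small, arch, sim.LibrarySimConfig(n_reads=1000, seed=4)
        )
        kept, qc = pp.preprocess_reads(lib.reads, trim_cfg, umi_len=arch.umi_len)
        assert qc.total == 1000
        assert sum(qc.counts.values()) == 1000
        assert len(kept) == qc.counts[TrimStatus.KEPT]
        assert len(qc.statuses) == 1000


class TestSubsample:
    def test_exact_count_and_order(self, rng):
        reads = [make_read("ACGT", read_id=f"r{i}") for i in range(1000)]
        out = list(pp.subsample_reads(reads, 300, seed=42))
        assert len(out) == 300
        ids = [int(r.read_id[1:]) for r in out]
        assert ids == sorted(ids)  # original order preserved

    def test_n_at_least_total_returns_all(self):
        reads = [make_read("ACGT", read_id=f"r{i}") for i in range(10)]
        assert len(list(pp.subsample_reads(reads, 10_000, seed=1))) == 10

    def test_deterministic_given_seed(self):
        reads = [make_read("ACGT", read_id=f"r{i}") for i in range(500)]
        a = [r.read_id for r in pp.subsample_reads(reads, 200, seed=42)]
        b = [r.read_id for r in pp.subsample_reads(reads, 200, seed=42)]
        c = [r.read_id for r in pp.subsample_reads(reads, 200, seed=43)]
        assert a == b
        assert a != c
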