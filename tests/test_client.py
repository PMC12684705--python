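"""Client pipeline: deployment geometry, query handling, extraction, filters."""

import json
import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from privkmer import client, server, synthetic
from privkmer.errors import (
    ConfigurationError,
    IncompleteResultsError,
    UsageError,
)
from privkmer.he import CryptoParams, create_context


def naive_find_all(haystack: str, needle: str) -> list[int]:
    """Independent oracle: str.find scan, case-folded, exact characters only."""
    hay, nee = haystack.upper(), needle.upper()
    out, i = [], hay.find(nee)
    while i != -1:
        out.append(i)
        i = hay.find(nee, i + 1)
    return out


def run_pipeline(tmp, input_path, kmers, ctx, keys, k_max, chunk_size,
                 quality_mode=None, quality_threshold=None, fastq=None):
    client.encrypt_input(input_path, ctx, keys, k_max, tmp / "deploy",
                         chunk_size=chunk_size, quality_mode=quality_mode)
    infos = client.encrypt_queries(kmers, ctx, keys, k_max, tmp / "queries",
                                   tmp / "registry.json")
    server.process_all(tmp / "deploy", tmp / "queries", tmp / "results")
    return client.decrypt_and_extract(
        tmp / "results", tmp / "deploy", ctx, keys, infos,
        quality_mode=quality_mode, quality_threshold=quality_threshold,
        fastq_path=fastq,
    ), infos


class TestEncryptInput:
    def test_deployment_geometry_1kb(self, tmp_path, clear_ctx, clear_keys):
        genome, _ = synthetic.make_genome(synthetic.GenomeSpec(seed=9, length=1024))
        fasta = tmp_path / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        client.encrypt_input(fasta, clear_ctx, clear_keys, 16, tmp_path / "d")
        man = json.load(open(tmp_path / "d" / "manifest.json"))
        n_batches = sum(len(c["batches"]) for c in man["chunks"])
        assert n_batches == math.ceil(1024 / clear_ctx.slot_count)
        cts = list((tmp_path / "d" / "chunks").glob("*_s*.ct"))
        assert len(cts) == n_batches * 16

    def test_no_plaintext_artifacts_in_deployment(self, tmp_path, clear_ctx,
                                                  clear_keys):
        plant = "ACGTACGTACGTACGTACGT"
        genome, _ = synthetic.make_genome(
            synthetic.GenomeSpec(seed=1, length=1500, plants=((plant, 200),))
        )
        fasta = tmp_path / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        client.encrypt_input(fasta, clear_ctx, clear_keys, 8, tmp_path / "d")
        for f in (tmp_path / "d").rglob("*"):
            if f.is_file():
                blob = f.read_bytes()
                assert genome[:80].encode() not in blob
                assert b"secret" not in blob.lower()

    def test_quality_strides_only_for_fastq_sum_mode(self, tmp_path, clear_ctx,
                                                     clear_keys):
        reads, _ = synthetic.make_reads(synthetic.ReadSetSpec(seed=2, n_reads=5,
                                                              read_length=40))
        fq = tmp_path / "r.fq"
        synthetic.write_fastq(fq, reads)
        client.encrypt_input(fq, clear_ctx, clear_keys, 6, tmp_path / "dq",
                             quality_mode="sum")
        assert list((tmp_path / "dq" / "chunks").glob("*_q*.ct"))
        client.encrypt_input(fq, clear_ctx, clear_keys, 6, tmp_path / "dmin",
                             quality_mode="min")
        assert not list((tmp_path / "dmin" / "chunks").glob("*_q*.ct"))
        genome, _ = synthetic.make_genome(synthetic.GenomeSpec(seed=3, length=500))
        fa = tmp_path / "g.fa"
        synthetic.write_fasta(fa, "c", genome)
        with pytest.raises(ConfigurationError):
            client.encrypt_input(fa, clear_ctx, clear_keys, 6, tmp_path / "dx",
                                 quality_mode="sum")


class TestEncryptQueries:
    def test_constant_slot_ciphertexts(self, tmp_path, clear_ctx, clear_keys):
        infos = client.encrypt_queries(["ACG"], clear_ctx, clear_keys, 8,
                                       tmp_path / "q", tmp_path / "reg.json")
        assert infos == [{"id": "0", "k": 3, "seq": "ACG"}]
        for j, expected in enumerate([0, 1, 2]):
            ct = clear_ctx.load_cipher(tmp_path / "q" / f"q0_{j}.ct")
            vec = clear_ctx.decrypt_vec(ct, clear_keys)
            assert np.all(vec == expected)

    def test_queries_dir_carries_no_plaintext(self, tmp_path, clear_ctx, clear_keys):
        client.encrypt_queries(["ACGTACGT"], clear_ctx, clear_keys, 8,
                               tmp_path / "q", tmp_path / "reg.json")
        with open(tmp_path / "q" / "queries.json") as fh:
            public = json.load(fh)
        assert "seq" not in json.dumps(public)
        assert json.load(open(tmp_path / "reg.json"))["queries"][0]["seq"] == "ACGTACGT"

    @pytest.mark.parametrize("bad", ["ACN", "", "ACGU"])
    def test_non_acgt_query_rejected(self, bad, tmp_path, clear_ctx, clear_keys):
        with pytest.raises(UsageError):
            client.encrypt_queries([bad], clear_ctx, clear_keys, 8,
                                   tmp_path / "q", None)

    def test_query_longer_than_kmax_rejected(self, tmp_path, clear_ctx, clear_keys):
        with pytest.raises(UsageError, match="k_max"):
            client.encrypt_queries(["ACGTACGTA"], clear_ctx, clear_keys, 8,
                                   tmp_path / "q", None)


class TestExtraction:
    def test_planted_positions_recovered_exactly(self, tmp_path, clear_ctx,
                                                 clear_keys):
        plant = "GATTACAGATTACA"
        genome, _ = synthetic.make_genome(
            synthetic.GenomeSpec(seed=11, length=3000,
                                 plants=((plant, 10), (plant, 500), (plant, 2980 - len(plant)),))
        )
        fasta = tmp_path / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        records, infos = run_pipeline(
            tmp_path, fasta, [plant, "ACACACACACACAC"], clear_ctx, clear_keys,
            k_max=16, chunk_size=1200,
        )
        found = sorted(r.position for r in records if r.query_id == "0")
        assert found == naive_find_all(genome, plant)
        absent = [r for r in records if r.query_id == "1"]
        assert absent == [] or sorted(r.position for r in absent) == naive_find_all(
            genome, "ACACACACACACAC"
        )

    def test_occurrence_in_chunk_overlap_reported_once(self, tmp_path, clear_ctx,
                                                       clear_keys):
        # place the plant so it straddles the chunk boundary region
        plant = "TTGGCCAA"
        genome, _ = synthetic.make_genome(
            synthetic.GenomeSpec(seed=12, length=2050, plants=((plant, 1018),))
        )
        fasta = tmp_path / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        records, _ = run_pipeline(tmp_path, fasta, [plant], clear_ctx, clear_keys,
                                  k_max=9, chunk_size=1024)
        positions = [r.position for r in records]
        assert positions.count(1018) == 1
        assert sorted(positions) == naive_find_all(genome, plant)

    def test_missing_result_file_reported(self, tmp_path, clear_ctx, clear_keys):
        genome, _ = synthetic.make_genome(synthetic.GenomeSpec(seed=13, length=800))
        fasta = tmp_path / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        client.encrypt_input(fasta, clear_ctx, clear_keys, 8, tmp_path / "deploy")
        infos = client.encrypt_queries(["ACGTACGT"], clear_ctx, clear_keys, 8,
                                       tmp_path / "queries", tmp_path / "reg.json")
        server.process_all(tmp_path / "deploy", tmp_path / "queries",
                           tmp_path / "results")
        next((tmp_path / "results").glob("q0_*.bin")).unlink()
        with pytest.raises(IncompleteResultsError):
            client.decrypt_and_extract(tmp_path / "results", tmp_path / "deploy",
                                       clear_ctx, clear_keys, infos)

    @settings(max_examples=8)
    @given(st.integers(0, 2**32))
    def test_end_to_end_equals_naive_search(self, clear_ctx, clear_keys,
                                            tmp_path_factory, seed):
        """Random genomes + planted/random queries: match set == naive scan."""
        rng = np.random.default_rng(seed)
        tmp = tmp_path_factory.mktemp(f"e2e{seed % 10_000}")
        k = int(rng.integers(4, 13))
        plant = "".join("ACGT"[b] for b in rng.integers(0, 4, k))
        genome, _ = synthetic.make_genome(
            synthetic.GenomeSpec(seed=seed, length=int(rng.integers(2000, 6000)),
                                 plants=((plant, None),))
        )
        fasta = tmp / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        queries = [plant] + synthetic.sample_queries(rng, genome, 2, 2, k)
        queries = list(dict.fromkeys(queries))
        records, infos = run_pipeline(tmp, fasta, queries, clear_ctx, clear_keys,
                                      k_max=16, chunk_size=1500)
        for info in infos:
            got = sorted(r.position for r in records if r.query_id == info["id"])
            assert got == naive_find_all(genome, info["seq"])
        report = client.verify_against_plaintext(fasta, infos, records)
        assert report["ok"]


class TestFastqAndQuality:
    @pytest.fixture
    def fastq_run(self, tmp_path, clear_ctx, clear_keys):
        plant = "ACGTACGTAC"
        spec = synthetic.ReadSetSpec(
            seed=21, n_reads=40, read_length=60, qual_mean=25, qual_sd=8,
            plants=((plant, 3, 10), (plant, 7, 50), (plant, 30, 0)),
        )
        reads, truth = synthetic.make_reads(spec)
        fq = tmp_path / "r.fq"
        synthetic.write_fastq(fq, reads)
        return tmp_path, fq, reads, plant

    def test_no_match_spans_read_boundary(self, fastq_run, clear_ctx, clear_keys):
        tmp, fq, reads, plant = fastq_run
        records, infos = run_pipeline(tmp, fq, [plant], clear_ctx, clear_keys,
                                      k_max=12, chunk_size=1024, fastq=fq)
        read_len = {rid: len(seq) for rid, seq, _ in reads}
        assert records, "expected planted matches"
        for r in records:
            assert r.position + r.k <= read_len[r.record_name]
        expected = {
            (rid, pos)
            for rid, seq, _ in reads for pos in naive_find_all(seq, plant)
        }
        assert {(r.record_name, r.position) for r in records} == expected

    @pytest.mark.parametrize("mode", ["min", "avg", "sum"])
    def test_quality_filters_match_plaintext_reference(self, mode, tmp_path_factory,
                                                       clear_ctx, clear_keys):
        plant = "ACGTACGTAC"
        spec = synthetic.ReadSetSpec(
            seed=33, n_reads=60, read_length=50, qual_mean=22, qual_sd=10,
            plants=tuple((plant, i, 5) for i in range(0, 60, 7)),
        )
        reads, _ = synthetic.make_reads(spec)
        tmp = tmp_path_factory.mktemp(f"qual_{mode}")
        fq = tmp / "r.fq"
        synthetic.write_fastq(fq, reads)
        threshold = {"min": 18, "avg": 23.5, "sum": 235}[mode]
        records, infos = run_pipeline(
            tmp, fq, [plant], clear_ctx, clear_keys, k_max=10, chunk_size=2000,
            quality_mode=mode, quality_threshold=threshold, fastq=fq,
        )
        # independent reference filter on the plaintext reads
        quals = {rid: [ord(c) - 33 for c in q] for rid, _, q in reads}
        survivors = set()
        for rid, seq, _ in reads:
            for pos in naive_find_all(seq, plant):
                window = quals[rid][pos: pos + len(plant)]
                if mode == "min":
                    ok = min(window) >= threshold
                elif mode == "sum":
                    ok = sum(window) >= threshold
                else:
                    ok = (sum(window) / len(plant)) >= threshold
                if ok:
                    survivors.add((rid, pos))
        assert {(r.record_name, r.position) for r in records} == survivors

    def test_avg_mode_uses_homomorphic_sums(self, fastq_run, clear_ctx, clear_keys):
        tmp, fq, reads, plant = fastq_run
        records, _ = run_pipeline(tmp, fq, [plant], clear_ctx, clear_keys,
                                  k_max=12, chunk_size=1024, quality_mode="avg",
                                  quality_threshold=1, fastq=fq)
        for r in records:
            assert r.hom_sum_q is not None
            assert r.hom_sum_q == r.sum_q  # decrypted sum equals plaintext sum


class TestVerification:
    def test_empty_query_list_gives_empty_report(self, tmp_path, clear_ctx,
                                                 clear_keys):
        genome, _ = synthetic.make_genome(synthetic.GenomeSpec(seed=5, length=400))
        fasta = tmp_path / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        report = client.verify_against_plaintext(fasta, [], [])
        assert report["ok"] and report["queries"] == {}

    def test_discrepancy_detected(self, tmp_path):
        genome, _ = synthetic.make_genome(synthetic.GenomeSpec(seed=6, length=400))
        fasta = tmp_path / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        fake = [client.MatchRecord(query_id="0", query_seq="ACGT",
                                   record_name="chr1", position=999,
                                   absolute=999, k=4)]
        report = client.verify_against_plaintext(
            fasta, [{"id": "0", "seq": "ACGT", "k": 4}], fake
        )
        assert not report["ok"]
        assert report["total_false_positives"] >= 1

    def test_results_tsv_layout(self, tmp_path, clear_ctx, clear_keys):
        plant = "GGGGCCCC"
        genome, _ = synthetic.make_genome(
            synthetic.GenomeSpec(seed=7, length=900, plants=((plant, 123),))
        )
        fasta = tmp_path / "g.fa"
        synthetic.write_fasta(fasta, "chr1", genome)
        records, _ = run_pipeline(tmp_path, fasta, [plant], clear_ctx, clear_keys,
                                  k_max=8, chunk_size=500)
        out = tmp_path / "hits.tsv"
        client.write_results_tsv(records, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t")[:4] == ["query_id", "query_seq",
                                            "source_record", "position"]
        assert any("\t123\t" in line for line in lines[1:])
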