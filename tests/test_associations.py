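import numpy as np
import pytest

from ncpmda import (
    AssociationNetwork,
    EdgeRecord,
    build_network,
    predict,
    read_association_edgelist,
    read_edge_records,
    read_score_table,
    write_edgelist,
    write_score_table,
)
from ncpmda.exceptions import EdgeListParseError

from conftest import make_network


def write_tsv(path, rows, header=None):
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


class TestEdgeListReading:
    def test_dedup_and_dimensions(self, tmp_path):
        p = tmp_path / "edges.tsv"
        write_tsv(p, [("d1", "m1"), ("d1", "m1"), ("d2", "m2")])
        net, report = build_network(read_edge_records(p))
        assert (net.nd, net.nm) == (2, 2)
        assert net.n_associations == 2
        assert report.duplicates_removed == 1
        assert report.rows_read == 3

    def test_first_appearance_ordering(self, tmp_path):
        p = tmp_path / "edges.tsv"
        write_tsv(p, [("d1", "m1"), ("d2", "m1"), ("d2", "m2")])
        net = read_association_edgelist(p)
        assert net.diseases == ("d1", "d2")
        assert net.microbes == ("m1", "m2")
        np.testing.assert_array_equal(net.A, [[1, 0], [1, 1]])

    def test_hmdad_scale_dedup(self, tmp_path):
        """A 483-row file engineered to contain 33 exact duplicate pairs
        collapses to 450 distinct associations (the curated-snapshot scale
        the method targets: 39 diseases, 292 microbes)."""
        rng = np.random.default_rng(450)
        pairs = set()
        while len(pairs) < 450:
            pairs.add((int(rng.integers(39)), int(rng.integers(292))))
        pairs = sorted(pairs)
        dup_idx = rng.choice(450, size=33, replace=False)
        rows = [(f"d{i}", f"m{j}") for i, j in pairs]
        rows += [rows[i] for i in dup_idx]
        assert len(rows) == 483
        p = tmp_path / "hmdad_like.tsv"
        write_tsv(p, rows)
        net, report = build_network(read_edge_records(p))
        assert report.rows_read == 483
        assert report.duplicates_removed == 33
        assert net.n_associations == 450

    def test_header_comments_and_whitespace(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text(
            "disease\tmicrobe\n# a comment\n\n d1 \t m1 \nd2\tm2\n",
            encoding="utf-8",
        )
        net = read_association_edgelist(p, header=True)
        assert net.diseases == ("d1", "d2")
        assert net.n_associations == 2

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("# only a comment\n", encoding="utf-8")
        with pytest.raises(EdgeListParseError, match="no association rows"):
            read_edge_records(p)

    def test_short_row_names_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("d1\tm1\njust-one-column\n", encoding="utf-8")
        with pytest.raises(EdgeListParseError, match="line 2"):
            read_edge_records(p)

    def test_dedup_is_idempotent(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tsv(p1, [("d1", "m1"), ("d1", "m1"), ("d2", "m2")])
        net = read_association_edgelist(p1)
        write_edgelist(net, p2)
        net2, report2 = build_network(read_edge_records(p2))
        assert report2.duplicates_removed == 0
        np.testing.assert_array_equal(net.A, net2.A)

    def test_row_and_column_sums_match_edge_counts(self, tmp_path):
        rows = [("d1", "m1"), ("d1", "m2"), ("d2", "m2"), ("d3", "m1")]
        p = tmp_path / "edges.tsv"
        write_tsv(p, rows)
        net = read_association_edgelist(p)
        for d, count in {"d1": 2, "d2": 1, "d3": 1}.items():
            assert net.A[net.disease_index[d]].sum() == count
        for m, count in {"m1": 2, "m2": 2}.items():
            assert net.A[:, net.microbe_index[m]].sum() == count


class TestNetworkValidation:
    @pytest.mark.parametrize(
        "diseases, microbes, A",
        [
            (("d1", "d1"), ("m1",), [[1], [0]]),       # duplicate labels
            (("d1",), ("m1", "m1"), [[1, 0]]),
            (("d1",), ("m1",), [[2]]),                 # non-binary entry
            (("d1", "d2"), ("m1",), [[1]]),            # shape mismatch
            ((), ("m1",), np.zeros((0, 1))),           # no diseases
        ],
    )
    def test_invalid_networks_rejected(self, diseases, microbes, A):
        with pytest.raises(ValueError):
            AssociationNetwork(diseases, microbes, np.asarray(A))

    def test_isolated_entities_permitted(self):
        net = make_network([[1, 0, 0], [0, 0, 0]])
        assert net.n_associations == 1

    def test_blank_label_rejected(self):
        with pytest.raises(ValueError):
            EdgeRecord("  ", "m1")

    def test_roundtrip_reproduces_matrix(self, rng, tmp_path):
        # any network whose entities all have at least one association
        # survives a write/read cycle bit-identically (modulo label order,
        # which first-appearance reading may permute)
        for trial in range(5):
            A = (rng.random((4, 6)) < 0.5).astype(int)
            A[A.sum(axis=1) == 0, 0] = 1
            A[0, A.sum(axis=0) == 0] = 1
            net = make_network(A)
            p = tmp_path / f"rt{trial}.tsv"
            write_edgelist(net, p)
            back = read_association_edgelist(p)
            perm_d = [back.disease_index[d] for d in net.diseases]
            perm_m = [back.microbe_index[m] for m in net.microbes]
            np.testing.assert_array_equal(
                np.asarray(back.A)[np.ix_(perm_d, perm_m)], net.A
            )


class TestScoreTable:
    def test_sorted_descending_within_disease(self, tmp_path):
        net = make_network([[0, 1], [1, 0]])
        scores = predict(net)
        sm = scores.S.copy()
        p = tmp_path / "scores.tsv"
        write_score_table(net, scores, p)
        table = read_score_table(p)
        assert len(table) == 4
        for _, group in table.groupby("disease", sort=False):
            assert (group["score"].diff().dropna() <= 0).all()
        first = table.iloc[0]
        assert first["disease"] == "d0"
        assert first["score"] == pytest.approx(sm[0].max(), abs=1e-6)

    def test_tie_break_by_microbe_label(self, tmp_path, identity_net):
        from ncpmda.projection import ScoreMatrix

        scores = ScoreMatrix(
            np.array([[0.5, 0.5], [0.1, 0.2]]),
            identity_net.diseases, identity_net.microbes, 1.0, 1.0,
        )
        p = tmp_path / "scores.tsv"
        write_score_table(identity_net, scores, p)
        table = read_score_table(p)
        assert list(table["microbe"][:2]) == ["m1", "m2"]

    def test_known_column_and_exclusion(self, tmp_path, identity_net):
        scores = predict(identity_net)
        p = tmp_path / "scores.tsv"
        write_score_table(identity_net, scores, p, include_known=False)
        table = read_score_table(p)
        assert (table["known"] == 0).all()
        assert len(table) == 2

    def test_roundtrip_to_twelve_decimals(self, tmp_path, rng):
        A = (rng.random((5, 8)) < 0.4).astype(int)
        A[0, 0] = 1
        net = make_network(A)
        scores = predict(net)
        p = tmp_path / "scores.tsv"
        write_score_table(net, scores, p, decimals=12)
        table = read_score_table(p)
        pivot = table.pivot(index="disease", columns="microbe", values="score")
        back = pivot.loc[list(net.diseases), list(net.microbes)].to_numpy()
        np.testing.assert_allclose(back, scores.S, atol=1e-12, rtol=0)

    def test_dimension_mismatch_rejected(self, tmp_path, identity_net):
        other = make_network([[1, 0, 0], [0, 1, 0]])
        with pytest.raises(ValueError, match="does not match"):
            write_score_table(identity_net, predict(other), tmp_path / "x.tsv")
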