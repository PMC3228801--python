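# comphot 0.1.0
# config_hash: 73efdcb41971
# seed: 5
# level: 0.99
# alpha: 0.05
id	virus	chr	arm	strand	start	end	length	n_in_win	n_out_win	n_in_lose	n_out_lose	OR	ci_low	ci_high	p_raw	p_adj	significant
hiv_2	HIV	chr1	p	-	548850	638652	89802	163	1237	26	1374	6.96356	4.57094	10.6086	5.32463e-27	2.12985e-26	True
mlv_1	MLV	chr1	p	+	1362839	1451028	88189	153	1247	22	1378	7.68514	4.88354	12.094	9.38605e-27	2.81581e-26	True
mlv_2	MLV	chr1	p	-	1360602	1438061	77459	152	1248	23	1377	7.29181	4.67205	11.3805	6.94903e-26	1.38981e-25	True
hiv_1	HIV	chr1	p	+	565966	645218	79252	138	1262	19	1381	7.94804	4.89046	12.9172	1.23037e-24	1.23037e-24	True
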