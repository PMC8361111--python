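peak_no	name	ygm_alias	acylation_class	rt_min	precursor_mz	aglycone_mzs	qualifying_mzs	core	glycosyls	acyls
1	Cyanidin-3-sophoroside-5-glucoside	YGM 0A	Non	1.11	773.21	287.05	449.11;611.16	cyanidin	hexose;hexose;hexose
2	Peonidin 3-sophoroside-5-glucoside	YGM 0B	Non	1.37	787.23	301.07	463.12;625.17	peonidin	hexose;hexose;hexose
3	Cyanidin-3-p-hydroxybenzoyl sophoroside-5-glucoside		Mono	1.60	893.23	287.05	449.11;731.18	cyanidin	hexose;hexose;hexose	p-hydroxybenzoyl
4	Cyanidin-3-caffeoyl sophoroside-5-glucoside	YGM 2	Mono	1.65	935.25	287.05	449.11;773.19	cyanidin	hexose;hexose;hexose	caffeoyl
5	Peonidin 3-p-hydroxybenzoyl sophoroside-5-glucoside		Mono	1.96	907.25	301.07	463.12;745.20	peonidin	hexose;hexose;hexose	p-hydroxybenzoyl
6	Peonidin 3-caffeoyl sophoroside-5-glucoside	YGM 5B	Mono	2.02	949.25	301.07	463.12;787.21	peonidin	hexose;hexose;hexose	caffeoyl
7	Cyanidin-3-feruloyl sophoroside-5-glucoside		Mono	2.24	949.25	287.05	449.11;787.21	cyanidin	hexose;hexose;hexose	feruloyl
8	Peonidin-3-feruloyl sophoroside-5-glucoside		Mono	2.99	963.27	301.07	463.12;801.22	peonidin	hexose;hexose;hexose	feruloyl
9	Cyanidin 3-caffeoyl sophoroside-5-glucoside	YGM 2	Mono	3.30	935.25	287.05	449.11;773.19	cyanidin	hexose;hexose;hexose	caffeoyl
10.1	Cyanidin 3-caffeoyl-p-hydroxybenzoyl sophoroside-5-glucoside	YGM 1A	Di	3.52	1055.27	287.06	449.11;893.21	cyanidin	hexose;hexose;hexose	caffeoyl;p-hydroxybenzoyl
10.2	Cyanidin 3-dicaffeoyl sophoroside-5-glucoside	YGM 1B	Di	3.55	1097.28	287.06	449.10;935.23	cyanidin	hexose;hexose;hexose	caffeoyl;caffeoyl
11	Peonidin 3-caffeoyl sophoroside-5-glucoside	YGM 5B	Mono	4.45	949.25	301.07	463.12;787.21	peonidin	hexose;hexose;hexose	caffeoyl
12.1	Peonidin 3-caffeoyl sophoroside-5-glucoside	YGM 5B	Mono	4.62	949.25	301.07	463.12;787.21	peonidin	hexose;hexose;hexose	caffeoyl
12.2	Cyanidin-3-caffeoyl-feruloyl sophoroside-5-glucoside	YGM 3	Di	4.62	1111.29	287.05	449.11;949.24	cyanidin	hexose;hexose;hexose	caffeoyl;feruloyl
13	Peonidin 3-dicaffeoyl sophoroside-5-glucoside	YGM 4B	Di	5.01	1111.29	301.07	463.12;949.24	peonidin	hexose;hexose;hexose	caffeoyl;caffeoyl
14	Peonidin 3-caffeoyl-p-hydroxybenzoyl sophoroside-5-glucoside	YGM 5A	Di	5.15	1069.28	301.07	463.12;907.23	peonidin	hexose;hexose;hexose	caffeoyl;p-hydroxybenzoyl
15	Peonidin-3-caffeoyl-feruloyl sophoroside-5-glucoside	YGM 6	Di	6.62	1125.31	301.07	463.12;963.25	peonidin	hexose;hexose;hexose	caffeoyl;feruloyl
16	Peonidin-3-caffeoyl-feruloyl sophoroside-5-glucoside OR Cyanidin 3-diferuloyl sophoroside-5-glucoside	YGM 6	Di	7.09	1125.31	287.05;301.07	449.11;963.25	peonidin|cyanidin	hexose;hexose;hexose	caffeoyl;feruloyl
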