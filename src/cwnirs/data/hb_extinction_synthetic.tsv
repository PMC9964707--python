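# Synthetic molar extinction coefficient table for hemoglobin, 650-1050 nm.
# Constructed in-package to be shape-accurate against the standard literature
# compilations of human hemoglobin optical absorption (deoxy-Hb peak near
# 760 nm, isosbestic crossing near 800 nm, HbO2 > Hb above ~830 nm); the
# individual values are smoothed representative numbers, not a digitization
# of any published table, and are intended for simulation and differential
# (concentration-change) analysis rather than absolute dosimetry.
# Basis: NATURAL LOG (values are log10-basis molar coefficients x ln 10).
# Units: mM^-1 cm^-1.  Columns: wavelength_nm  HbO2  Hb  THb (THb = HbO2 + Hb).
wavelength_nm	HbO2	Hb	THb
650	0.847351	8.634694	9.482045
655	0.784816	8.004812	8.789628
660	0.736827	7.430442	8.167269
665	0.702887	6.915759	7.618646
670	0.676960	6.438028	7.114988
675	0.653861	5.980660	6.634521
680	0.640119	5.544625	6.184744
685	0.636793	5.114003	5.750796
690	0.635513	4.724905	5.360418
695	0.646324	4.414100	5.060424
700	0.667750	4.130838	4.798588
705	0.696371	3.841020	4.537391
710	0.729919	3.566704	4.296623
715	0.758982	3.327776	4.086758
720	0.792089	3.090069	3.882158
725	0.840305	2.749781	3.590086
730	0.898008	2.537449	3.435457
735	0.958886	2.545880	3.504766
740	1.026953	2.569685	3.596638
745	1.107848	2.854769	3.962617
750	1.192739	3.235132	4.427871
755	1.272179	3.456244	4.728423
760	1.349315	3.566704	4.916019
765	1.424150	3.333732	4.757882
770	1.496680	2.965730	4.462410
775	1.568596	2.711591	4.280187
780	1.634835	2.475279	4.110114
785	1.687795	2.234494	3.922289
790	1.740754	2.026275	3.767029
795	1.809470	1.866857	3.676327
800	1.878909	1.754570	3.633479
805	1.935154	1.692771	3.627925
810	1.989434	1.650954	3.640388
815	2.047886	1.615712	3.663598
820	2.109168	1.597994	3.707162
825	2.176607	1.597994	3.774601
830	2.242718	1.597994	3.840712
835	2.301257	1.597227	3.898484
840	2.353242	1.595691	3.948933
845	2.396465	1.593005	3.989470
850	2.436135	1.591086	4.027221
855	2.475279	1.591700	4.066979
860	2.514423	1.593389	4.107812
865	2.557245	1.605304	4.162549
870	2.597316	1.625625	4.222941
875	2.628756	1.647783	4.276539
880	2.657183	1.671677	4.328860
885	2.685719	1.693995	4.379714
890	2.712445	1.715426	4.427871
895	2.735244	1.734536	4.469780
900	2.758497	1.754570	4.513067
905	2.785867	1.779076	4.564943
910	2.818364	1.807529	4.625893
915	2.864005	1.842351	4.706356
920	2.910468	1.878909	4.789377
925	2.946812	1.911555	4.858367
930	2.974940	1.943382	4.918322
935	2.996431	1.977370	4.973801
940	3.007176	2.007854	5.015030
945	3.001154	2.032294	5.033448
950	2.988755	2.049301	5.038056
955	2.970765	2.058799	5.029564
960	2.947309	2.063116	5.010425
965	2.921652	2.058799	4.980451
970	2.892047	2.049301	4.941348
975	2.857063	2.031908	4.888971
980	2.818364	2.007854	4.826218
985	2.777807	1.981741	4.759548
990	2.735471	1.952592	4.688063
995	2.692564	1.921254	4.613818
1000	2.647973	1.888120	4.536093
1005	2.600504	1.854157	4.454661
1010	2.551264	1.819042	4.370306
1015	2.501183	1.782498	4.283681
1020	2.449951	1.745360	4.195311
1025	2.397285	1.708518	4.105803
1030	2.344032	1.671677	4.015709
1035	2.291072	1.634835	3.925907
1040	2.238113	1.597994	3.836107
1045	2.185153	1.561153	3.746306
1050	2.132194	1.524311	3.656505
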