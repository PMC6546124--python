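clade_id	species_id	n_genes	n_pseudogenes	lineage_specific_duplicate	rnai_lethal
CG1441	Dmel	1	0	0	0
CG1441	Dsim	1	0	0	0
CG1441	Dsec	1	0	0	0
CG1441	Dyak	1	0	0	0
CG1441	Dere	1	0	0	0
CG1441	Dana	1	0	0	0
CG1441	Dpse	1	0	0	0
CG1441	Dper	1	0	0	0
CG1441	Dwil	1	0	0	0
CG1441	Dvir	1	0	0	0
CG1441	Dmoj	1	0	0	0
CG1441	Dgri	1	0	0	0
CG1443	Dmel	1	0	0	1
CG1443	Dsim	1	0	0	1
CG1443	Dsec	1	0	0	1
CG1443	Dyak	1	0	0	1
CG1443	Dere	1	0	0	1
CG1443	Dana	1	0	0	1
CG1443	Dpse	1	0	0	1
CG1443	Dper	1	0	0	1
CG1443	Dwil	1	0	0	1
CG1443	Dvir	1	0	0	1
CG1443	Dmoj	1	0	0	1
CG1443	Dgri	1	0	0	1
CG4020	Dmel	1	0	0	1
CG4020	Dsim	1	0	0	1
CG4020	Dsec	1	0	0	1
CG4020	Dyak	1	0	0	1
CG4020	Dere	1	0	0	1
CG4020	Dana	1	0	0	1
CG4020	Dpse	1	0	0	1
CG4020	Dper	1	0	0	1
CG4020	Dwil	1	0	0	1
CG4020	Dvir	1	0	0	1
CG4020	Dmoj	1	0	0	1
CG4020	Dgri	1	0	0	1
CG4770	Dmel	1	0	0	1
CG4770	Dsim	1	0	0	1
CG4770	Dsec	1	0	0	1
CG4770	Dyak	1	0	0	1
CG4770	Dere	1	0	0	1
CG4770	Dana	1	0	0	1
CG4770	Dpse	1	0	0	1
CG4770	Dper	1	0	0	1
CG4770	Dwil	1	0	0	1
CG4770	Dvir	1	0	0	1
CG4770	Dmoj	1	0	0	1
CG4770	Dgri	1	0	0	1
CG5065	Dmel	1	0	0	1
CG5065	Dsim	1	0	0	1
CG5065	Dsec	1	0	0	1
CG5065	Dyak	1	0	0	1
CG5065	Dere	1	0	0	1
CG5065	Dana	1	0	0	1
CG5065	Dpse	1	0	0	1
CG5065	Dper	1	0	0	1
CG5065	Dwil	1	0	0	1
CG5065	Dvir	1	0	0	1
CG5065	Dmoj	1	0	0	1
CG5065	Dgri	1	0	0	1
CG8303	Dmel	1	0	0	1
CG8303	Dsim	1	0	0	1
CG8303	Dsec	1	0	0	1
CG8303	Dyak	1	0	0	1
CG8303	Dere	1	0	0	1
CG8303	Dana	1	0	0	1
CG8303	Dpse	1	0	0	1
CG8303	Dper	1	0	0	1
CG8303	Dwil	1	0	0	1
CG8303	Dvir	1	0	0	1
CG8303	Dmoj	1	0	0	1
CG8303	Dgri	1	0	0	1
CG8306	Dmel	1	0	0	1
CG8306	Dsim	1	0	0	1
CG8306	Dsec	1	0	0	1
CG8306	Dyak	1	0	0	1
CG8306	Dere	1	0	0	1
CG8306	Dana	1	0	0	1
CG8306	Dpse	1	0	0	1
CG8306	Dper	1	0	0	1
CG8306	Dwil	1	0	0	1
CG8306	Dvir	1	0	0	1
CG8306	Dmoj	1	0	0	1
CG8306	Dgri	1	0	0	1
CG10096	Dmel	1	0	0	1
CG10096	Dsim	1	0	0	1
CG10096	Dsec	1	0	0	1
CG10096	Dyak	1	0	0	1
CG10096	Dere	1	0	0	1
CG10096	Dana	1	0	0	1
CG10096	Dpse	1	0	0	1
CG10096	Dper	1	0	0	1
CG10096	Dwil	1	0	0	1
CG10096	Dvir	8	0	0	1
CG10096	Dmoj	1	0	0	1
CG10096	Dgri	1	0	0	1
CG12268	Dmel	1	0	0	1
CG12268	Dsim	1	0	0	1
CG12268	Dsec	1	0	0	1
CG12268	Dyak	1	0	0	1
CG12268	Dere	1	0	0	1
CG12268	Dana	1	0	0	1
CG12268	Dpse	1	0	0	1
CG12268	Dper	1	0	0	1
CG12268	Dwil	1	0	0	1
CG12268	Dvir	1	0	0	1
CG12268	Dmoj	1	0	0	1
CG12268	Dgri	1	0	0	1
CG18031	Dmel	1	0	0	0
CG18031	Dsim	1	0	0	0
CG18031	Dsec	1	0	0	0
CG18031	Dyak	1	0	0	0
CG18031	Dere	1	0	0	0
CG18031	Dana	1	0	0	0
CG18031	Dpse	1	0	0	0
CG18031	Dper	1	0	0	0
CG18031	Dwil	1	0	0	0
CG18031	Dvir	1	0	0	0
CG18031	Dmoj	1	0	0	0
CG18031	Dgri	1	0	0	0
CG30427	Dmel	1	0	0	0
CG30427	Dsim	1	0	0	0
CG30427	Dsec	1	0	0	0
CG30427	Dyak	1	0	0	0
CG30427	Dere	1	0	0	0
CG30427	Dana	1	0	0	0
CG30427	Dpse	1	0	0	0
CG30427	Dper	1	0	0	0
CG30427	Dwil	1	0	0	0
CG30427	Dvir	1	0	0	0
CG30427	Dmoj	1	0	0	0
CG30427	Dgri	1	0	0	0
CG34342	Dmel	1	0	0	1
CG34342	Dsim	1	0	0	1
CG34342	Dsec	1	0	0	1
CG34342	Dyak	1	0	0	1
CG34342	Dere	1	0	0	1
CG34342	Dana	1	0	0	1
CG34342	Dpse	1	0	0	1
CG34342	Dper	1	0	0	1
CG34342	Dwil	1	0	0	1
CG34342	Dvir	1	0	0	1
CG34342	Dmoj	1	0	0	1
CG34342	Dgri	1	0	0	1
CG13091	Dmel	1	0	0	0
CG13091	Dsim	1	0	0	0
CG13091	Dsec	1	0	0	0
CG13091	Dyak	1	0	0	0
CG13091	Dere	1	0	0	0
CG13091	Dana	0	0	0	0
CG13091	Dpse	1	0	0	0
CG13091	Dper	1	0	0	0
CG13091	Dwil	1	0	0	0
CG13091	Dvir	0	0	0	0
CG13091	Dmoj	0	0	0	0
CG13091	Dgri	0	0	0	0
CG10097	Dmel	1	0	1	0
CG10097	Dsim	1	0	1	0
CG10097	Dsec	0	1	1	0
CG10097	Dyak	1	0	1	0
CG10097	Dere	1	0	1	0
CG10097	Dana	0	0	1	0
CG10097	Dpse	0	0	1	0
CG10097	Dper	0	0	1	0
CG10097	Dwil	0	0	1	0
CG10097	Dvir	0	0	1	0
CG10097	Dmoj	0	0	1	0
CG10097	Dgri	0	0	1	0
CG14893	Dmel	1	0	0	0
CG14893	Dsim	1	0	0	0
CG14893	Dsec	1	0	0	0
CG14893	Dyak	1	0	0	0
CG14893	Dere	1	0	0	0
CG14893	Dana	3	0	0	0
CG14893	Dpse	1	0	0	0
CG14893	Dper	1	0	0	0
CG14893	Dwil	1	0	0	0
CG14893	Dvir	1	0	0	0
CG14893	Dmoj	0	0	0	0
CG14893	Dgri	0	0	0	0
CG17560	Dmel	1	0	1	1
CG17560	Dsim	1	0	1	1
CG17560	Dsec	1	0	1	1
CG17560	Dyak	1	0	1	1
CG17560	Dere	1	0	1	1
CG17560	Dana	1	0	1	1
CG17560	Dpse	0	0	1	1
CG17560	Dper	0	0	1	1
CG17560	Dwil	0	0	1	1
CG17560	Dvir	0	0	1	1
CG17560	Dmoj	0	0	1	1
CG17560	Dgri	0	0	1	1
CG17562	Dmel	1	0	1	0
CG17562	Dsim	1	0	1	0
CG17562	Dsec	1	0	1	0
CG17562	Dyak	1	0	1	0
CG17562	Dere	1	0	1	0
CG17562	Dana	1	0	1	0
CG17562	Dpse	0	0	1	0
CG17562	Dper	0	0	1	0
CG17562	Dwil	0	0	1	0
CG17562	Dvir	0	0	1	0
CG17562	Dmoj	0	0	1	0
CG17562	Dgri	0	0	1	0
GJ13738	Dmel	0	0	0	
GJ13738	Dsim	0	0	0	
GJ13738	Dsec	0	0	0	
GJ13738	Dyak	0	0	0	
GJ13738	Dere	0	0	0	
GJ13738	Dana	0	0	0	
GJ13738	Dpse	0	0	0	
GJ13738	Dper	0	0	0	
GJ13738	Dwil	1	0	0	
GJ13738	Dvir	1	0	0	
GJ13738	Dmoj	1	0	0	
GJ13738	Dgri	1	0	0	
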