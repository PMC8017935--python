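class	term_id	name
biofilm	GO:0700001	biofilm formation
biofilm	GO:0700002	regulation of biofilm formation
biofilm	GO:0700003	positive regulation of biofilm formation
biofilm	GO:0700004	negative regulation of biofilm formation
biofilm	GO:0700005	single-species biofilm formation
biofilm	GO:0700006	multi-species biofilm formation
biofilm	GO:0700007	assembly biofilm formation
biofilm	GO:0700008	organization biofilm formation
biofilm	GO:0700009	biosynthetic process biofilm formation
biofilm	GO:0700010	production biofilm formation
biofilm	GO:0700011	export biofilm formation
biofilm	GO:0700012	secretion biofilm formation
biofilm	GO:0700013	biofilm matrix
biofilm	GO:0700014	biofilm matrix regulation of
biofilm	GO:0700015	biofilm matrix positive regulation of
biofilm	GO:0700016	biofilm matrix negative regulation of
biofilm	GO:0700017	biofilm matrix single-species
biofilm	GO:0700018	biofilm matrix multi-species
biofilm	GO:0700019	biofilm matrix assembly
biofilm	GO:0700020	biofilm matrix organization
biofilm	GO:0700021	biofilm matrix biosynthetic process
biofilm	GO:0700022	biofilm matrix production
biofilm	GO:0700023	biofilm matrix export
biofilm	GO:0700024	biofilm matrix secretion
biofilm	GO:0700025	extracellular polysaccharide
biofilm	GO:0700026	extracellular polysaccharide regulation of
biofilm	GO:0700027	extracellular polysaccharide positive regulation of
biofilm	GO:0700028	extracellular polysaccharide negative regulation of
biofilm	GO:0700029	extracellular polysaccharide single-species
biofilm	GO:0700030	extracellular polysaccharide multi-species
biofilm	GO:0700031	extracellular polysaccharide assembly
biofilm	GO:0700032	extracellular polysaccharide organization
biofilm	GO:0700033	extracellular polysaccharide biosynthetic process
biofilm	GO:0700034	extracellular polysaccharide production
biofilm	GO:0700035	extracellular polysaccharide export
biofilm	GO:0700036	extracellular polysaccharide secretion
biofilm	GO:0700037	cell aggregation
biofilm	GO:0700038	regulation of cell aggregation
biofilm	GO:0700039	positive regulation of cell aggregation
biofilm	GO:0700040	negative regulation of cell aggregation
biofilm	GO:0700041	single-species cell aggregation
biofilm	GO:0700042	multi-species cell aggregation
biofilm	GO:0700043	assembly cell aggregation
biofilm	GO:0700044	organization cell aggregation
biofilm	GO:0700045	biosynthetic process cell aggregation
biofilm	GO:0700046	production cell aggregation
biofilm	GO:0700047	export cell aggregation
biofilm	GO:0700048	secretion cell aggregation
quorum_sensing	GO:0700049	quorum sensing
quorum_sensing	GO:0700050	quorum sensing signal generation
quorum_sensing	GO:0700051	quorum sensing signal transduction
quorum_sensing	GO:0700052	quorum sensing autoinducer production
quorum_sensing	GO:0700053	quorum sensing response regulation
secretion_systems	GO:0700054	type I secretion system
secretion_systems	GO:0700055	type II secretion system
secretion_systems	GO:0700056	type III secretion system
secretion_systems	GO:0700057	type IV secretion system
secretion_systems	GO:0700058	type V secretion system
secretion_systems	GO:0700059	type VI secretion system
secretion_systems	GO:0700060	type VII secretion system
secretion_systems	GO:0700061	type VIII secretion system
secretion_systems	GO:0700062	type IX secretion system
secretion_systems	GO:0700063	protein secretion system assembly
secretion_systems	GO:0700064	secretion system regulation
siderophores	GO:0700065	siderophore biosynthetic process
siderophores	GO:0700066	siderophore transport
siderophores	GO:0700067	siderophore uptake
siderophores	GO:0700068	siderophore export
siderophores	GO:0700069	siderophore receptor activity
siderophores	GO:0700070	siderophore regulation
siderophores	GO:0700071	siderophore iron import
siderophores	GO:0700072	siderophore binding
siderophores	GO:0700073	siderophore transmembrane transporter activity
siderophores	GO:0700074	siderophore utilization
siderophores	GO:0700075	siderophore piracy
siderophores	GO:0700076	siderophore storage
siderophores	GO:0700077	siderophore recycling
siderophores	GO:0700078	siderophore esterase activity
siderophores	GO:0700079	siderophore synthesis
siderophores	GO:0700080	biosynthetic process siderophore transport
siderophores	GO:0700081	transport siderophore transport
siderophores	GO:0700082	uptake siderophore transport
siderophores	GO:0700083	export siderophore transport
siderophores	GO:0700084	receptor activity siderophore transport
siderophores	GO:0700085	regulation siderophore transport
siderophores	GO:0700086	iron import siderophore transport
siderophores	GO:0700087	binding siderophore transport
siderophores	GO:0700088	transmembrane transporter activity siderophore transport
siderophores	GO:0700089	utilization siderophore transport
siderophores	GO:0700090	piracy siderophore transport
siderophores	GO:0700091	storage siderophore transport
siderophores	GO:0700092	recycling siderophore transport
siderophores	GO:0700093	esterase activity siderophore transport
antibiotic_degradation	GO:0700094	antibiotic degradation
antibiotic_degradation	GO:0700095	extracellular antibiotic degradation
antibiotic_degradation	GO:0700096	periplasmic antibiotic degradation
antibiotic_degradation	GO:0700097	regulation of antibiotic degradation
antibiotic_degradation	GO:0700098	secreted antibiotic degradation
antibiotic_degradation	GO:0700099	enzymatic antibiotic degradation
antibiotic_degradation	GO:0700100	activity antibiotic degradation
antibiotic_degradation	GO:0700101	aminoglycoside antibiotic degradation
antibiotic_degradation	GO:0700102	macrolide antibiotic degradation
antibiotic_degradation	GO:0700103	tetracycline antibiotic degradation
antibiotic_degradation	GO:0700104	antibiotic catabolic process
antibiotic_degradation	GO:0700105	antibiotic catabolic process extracellular
antibiotic_degradation	GO:0700106	antibiotic catabolic process periplasmic
antibiotic_degradation	GO:0700107	antibiotic catabolic process regulation of
antibiotic_degradation	GO:0700108	antibiotic catabolic process secreted
antibiotic_degradation	GO:0700109	antibiotic catabolic process enzymatic
antibiotic_degradation	GO:0700110	antibiotic catabolic process activity
antibiotic_degradation	GO:0700111	antibiotic catabolic process aminoglycoside
antibiotic_degradation	GO:0700112	antibiotic catabolic process macrolide
antibiotic_degradation	GO:0700113	antibiotic catabolic process tetracycline
antibiotic_degradation	GO:0700114	beta-lactamase
antibiotic_degradation	GO:0700115	beta-lactamase extracellular
antibiotic_degradation	GO:0700116	beta-lactamase periplasmic
antibiotic_degradation	GO:0700117	beta-lactamase regulation of
antibiotic_degradation	GO:0700118	beta-lactamase secreted
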