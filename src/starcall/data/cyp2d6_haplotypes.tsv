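# Built-in CYP2D6 haplotype translation table.
# Dialect: TSV; '#' comments; empty site cell = reference state;
# 'var' = variant state; 'absent' = site not carried in interrogable
# form (CYP2D7-derived or uncharacterized hybrid sequence).
star_name	gene	structural_kind	switch_interval	tandem_partners	activity	rs1080985	rs769258	rs1065852	rs5030867	137_138insT	rs5030863	rs28371706	rs61736512	rs5030655	1758G>T	1758G>A	rs3892097	rs72549356	1863insTTTCGCCCC	rs72549354	rs72549353	rs35742686	rs5030656	rs16947	rs5030862	rs28371725	rs59421388	3198C>G	3277T>C	4042G>A	rs1135840
*1	CYP2D6	full_gene			1																										
*2	CYP2D6	full_gene			1																			var							var
*2.001	CYP2D6	full_gene			1	var																		var							var
*3	CYP2D6	full_gene			0																	var									
*4	CYP2D6	full_gene			0			var									var														var
*4.013	CYP2D6	hybrid_2D6_2D7	intron6..exon9	*4	0			var		var							var											absent	absent	absent	absent
*5	CYP2D6	deletion			0																										
*6	CYP2D6	full_gene			0									var																	
*7	CYP2D6	full_gene			0																				var						
*8	CYP2D6	full_gene			0										var									var							var
*9	CYP2D6	full_gene			0.5																		var								
*10	CYP2D6	full_gene			0.25			var																							var
*11	CYP2D6	full_gene			0						var													var							var
*12	CYP2D6	full_gene			0				var															var							var
*13	CYP2D6	hybrid_2D7_2D6	intron2..intron6	*2	0	absent	var			var			absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent		absent	absent	absent	var
*13[EU093102]	CYP2D6	hybrid_2D7_2D6	intron2..intron6		0	absent	var			var		absent			absent	absent		absent	absent	absent	absent		absent			absent		absent	absent	absent	var
*13[GQ162807]	CYP2D6	hybrid_2D7_2D6	intron2..intron6	*2	0	absent	var			var		absent			absent	absent		absent	absent	absent	absent		absent	var				absent	absent	absent	var
*14	CYP2D6	full_gene			0.5											var								var							var
*15	CYP2D6	full_gene			0					var																					
*17	CYP2D6	full_gene			0.5							var												var							var
*19	CYP2D6	full_gene			0																var			var							var
*20	CYP2D6	full_gene			0		var													var				var							var
*25	CYP2D6	full_gene			uncertain																							var			
*26	CYP2D6	full_gene			uncertain																								var		
*29	CYP2D6	full_gene			0.5								var											var			var				var
*30	CYP2D6	full_gene			uncertain														var												
*31	CYP2D6	full_gene			0																			var						var	var
*35	CYP2D6	full_gene			1		var																	var							var
*36	CYP2D6	hybrid_2D6_2D7	intron6..exon9	*10	0			var																			absent	absent	absent	absent	absent
*39.001	CYP2D6	full_gene			1																										var
*39.002	CYP2D6	full_gene			1	var																									var
*40	CYP2D6	full_gene			0							var						var						var							var
*41	CYP2D6	full_gene			0.25																			var		var					var
*57	CYP2D6	hybrid_2D6_2D7	intron6..exon9		uncertain			var																				absent	absent	absent	absent
*61	CYP2D6	hybrid_2D6_2D7	intron2..intron6		0								absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent
*63	CYP2D6	hybrid_2D6_2D7	intron2..intron6		0			var					absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent
*68	CYP2D6	hybrid_2D6_2D7	five_prime_flank..intron2	*4	0			var					absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent	absent
*69	CYP2D6	full_gene			0			var																var		var					var
*70	CYP2D6	full_gene			uncertain							var																			var
*83	CYP2D6	hybrid_2D6_2D7	intron6..exon9		0																			var				absent	absent	absent	absent
*107	CYP2D6	full_gene			uncertain																				var						var
*114	CYP2D6	full_gene			0			var								var								var							var
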