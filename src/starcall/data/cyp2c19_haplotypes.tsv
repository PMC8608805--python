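# Built-in CYP2C19 haplotype translation table.
# Dialect: TSV; '#' comments; empty site cell = reference state;
# 'var' = variant state; 'absent' = site not carried in interrogable
# form (CYP2D7-derived or uncharacterized hybrid sequence).
star_name	gene	structural_kind	switch_interval	tandem_partners	activity	rs12248560	rs28399504	rs12769205	rs41291556	rs72552267	rs17884712	rs4986893	rs6413438	rs4244285	rs72558186	rs56337013
*1	CYP2C19	full_gene			1											
*2	CYP2C19	full_gene			0									var		
*2.002	CYP2C19	full_gene			0			var						var		
*3	CYP2C19	full_gene			0							var				
*4	CYP2C19	full_gene			0		var									
*5	CYP2C19	full_gene			0											var
*6	CYP2C19	full_gene			0					var						
*7	CYP2C19	full_gene			0										var	
*8	CYP2C19	full_gene			0				var							
*9	CYP2C19	full_gene			0.5						var					
*10	CYP2C19	full_gene			0.5								var			
*17	CYP2C19	full_gene			1.5	var										
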