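pdb_id,aa_elect,aa_elect_sd,aa_vdw,aa_vdw_sd,aa_total,aa_total_sd,cg_elect,cg_elect_sd,cg_vdw,cg_vdw_sd,cg_total,cg_total_sd
1GMN,-3354.6,80.1,-42.2,4.8,-92.6,7.8,-3625.8,84.3,-53.2,4.7,-98.8,9.0
1HM2,-458.6,46.3,-47.2,6.5,-22.4,10.5,-539.4,9.8,-61.7,9.8,-80.6,14.8
1LOH,-42.5,34.1,-76.5,6.6,-55.6,11.7,-103.3,6.3,-31.8,34.4,-109.8,9.7
1OFM,-746.5,52.8,-27.7,3.8,-42.1,9.9,-767.2,47.9,-27.2,6.2,-50.9,12.3
2D8L,-30.7,21.2,-25.3,3.9,-5.5,9.9,-44.9,35.7,-35.1,5.3,-40.2,10.7
2NWG,-1737.9,102.4,-22.4,5.2,-55.5,18.5,-2334.1,126.6,-33.5,8.1,-94.4,19.6
2NWG,-1096.7,57.7,-21.5,2.9,-25.1,6.6,-1158.5,106.6,-35.4,7.3,-57.9,12.8
3ANK,3.9,45.1,-41.0,4.5,-22.1,7.0,-83.7,48.4,-52.9,6.5,-88.6,16.9
3OGX,-1235.8,35.7,-53.9,4.3,-51.6,8.7,-1351.7,53.6,-54.3,5.0,-57.3,11.1
3OJV,-5701.5,175.0,-86.0,6.6,-194.9,14.5,-5978.7,148.1,-88.4,6.2,-233.2,15.6
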