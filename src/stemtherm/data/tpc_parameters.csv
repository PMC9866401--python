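species,stage,model,parameter,estimate,stderr
chilo_partellus,egg,kontodimas_04,a,4.7e-5,1.2e-5
chilo_partellus,egg,kontodimas_04,CTmin,10.4,1.2
chilo_partellus,egg,kontodimas_04,CTmax,42.3,1.5
chilo_partellus,egg,kontodimas_04,Topt,31.6,
chilo_partellus,larva,briere1_99,a,3.3e-5,4.2e-6
chilo_partellus,larva,briere1_99,CTmin,13.5,1.3
chilo_partellus,larva,briere1_99,CTmax,37.1,0.6
chilo_partellus,larva,briere1_99,Topt,31.4,
chilo_partellus,pupa,briere1_99,a,8.7e-5,9.8e-6
chilo_partellus,pupa,briere1_99,CTmin,11.4,1.2
chilo_partellus,pupa,briere1_99,CTmax,38.3,0.7
chilo_partellus,pupa,briere1_99,Topt,32.1,
busseola_fusca,egg,kontodimas_04,a,2.2e-5,9.1e-5
busseola_fusca,egg,kontodimas_04,CTmin,5.9,1.7
busseola_fusca,egg,kontodimas_04,CTmax,42.2,3.7
busseola_fusca,egg,kontodimas_04,Topt,30.0,
busseola_fusca,larva,briere1_99,a,2.1e-5,1.0e-5
busseola_fusca,larva,briere1_99,CTmin,9.2,4.3
busseola_fusca,larva,briere1_99,CTmax,33.2,2.6
busseola_fusca,larva,briere1_99,Topt,27.7,
busseola_fusca,pupa,briere1_99,a,5.5e-5,8.4e-6
busseola_fusca,pupa,briere1_99,CTmin,8.0,1.5
busseola_fusca,pupa,briere1_99,CTmax,33.5,0.8
busseola_fusca,pupa,briere1_99,Topt,27.8,
ostrinia_nubilalis,egg,kontodimas_04,a,3.3e-5,1.2e-5
ostrinia_nubilalis,egg,kontodimas_04,CTmin,8.0,1.7
ostrinia_nubilalis,egg,kontodimas_04,CTmax,46.8,3.4
ostrinia_nubilalis,egg,kontodimas_04,Topt,33.8,
ostrinia_nubilalis,larva,briere1_99,a,2.1e-5,7.6e-6
ostrinia_nubilalis,larva,briere1_99,CTmin,7.9,3.2
ostrinia_nubilalis,larva,briere1_99,CTmax,44.2,6.0
ostrinia_nubilalis,larva,briere1_99,Topt,35.0,
ostrinia_nubilalis,pupa,perf2_11,c,8.8e-3,8.3e-4
ostrinia_nubilalis,pupa,perf2_11,k,0.92,1.0
ostrinia_nubilalis,pupa,perf2_11,CTmin,11.8,1.1
ostrinia_nubilalis,pupa,perf2_11,CTmax,36.3,1.5
ostrinia_nubilalis,pupa,perf2_11,Topt,33.0,
sesamia_nonagrioides,egg,kontodimas_04,a,1.6e-5,8.7e-6
sesamia_nonagrioides,egg,kontodimas_04,CTmin,5.6,2.8
sesamia_nonagrioides,egg,kontodimas_04,CTmax,46.7,5.0
sesamia_nonagrioides,egg,kontodimas_04,Topt,32.9,
sesamia_nonagrioides,larva,kontodimas_04,a,5.6e-6,1.6e-6
sesamia_nonagrioides,larva,kontodimas_04,CTmin,7.8,1.5
sesamia_nonagrioides,larva,kontodimas_04,CTmax,41.9,1.7
sesamia_nonagrioides,larva,kontodimas_04,Topt,30.5,
sesamia_nonagrioides,pupa,briere1_99,a,1.2e-5,3.3e-6
sesamia_nonagrioides,pupa,briere1_99,CTmin,5.7,1.3
sesamia_nonagrioides,pupa,briere1_99,CTmax,44.0,2.6
sesamia_nonagrioides,pupa,briere1_99,Topt,31.0,
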