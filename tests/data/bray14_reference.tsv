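sample_id	s1	s2	s3	s4	s5	s6	s7	s8	s9	s10	s11	s12	s13	s14
s1	0	0.096469523586	0.311367452531	0.615127280115	0.372385881847	0.429502510543	0.447420731467	0.225852469886	0.597221718213	0.277365547967	0.528553057623	0.436533293762	0.291335789592	0.534655267839
s2	0.096469523586	0	0.291578757281	0.627621772295	0.431859614332	0.412989428055	0.411030388812	0.264974209713	0.578722210972	0.235297768439	0.491048286113	0.459440859332	0.266301994256	0.503654278892
s3	0.311367452531	0.291578757281	0	0.570881801132	0.662309578157	0.497232329494	0.483929362909	0.344970801143	0.605830191994	0.301397311771	0.632744866937	0.472464191245	0.393039288833	0.533882036897
s4	0.615127280115	0.627621772295	0.570881801132	0	0.529565387231	0.586285539004	0.53096766263	0.543080141324	0.626639615772	0.608687385207	0.694829244913	0.463209687832	0.421278678832	0.708177250009
s5	0.372385881847	0.431859614332	0.662309578157	0.529565387231	0	0.545491202972	0.503250157687	0.438518479885	0.631550148617	0.466802556302	0.539765952436	0.46686107764	0.456886335117	0.685821465555
s6	0.429502510543	0.412989428055	0.497232329494	0.586285539004	0.545491202972	0	0.522301352243	0.398146984048	0.569993453258	0.576365863081	0.433367540712	0.482267692038	0.278852116252	0.300774593138
s7	0.447420731467	0.411030388812	0.483929362909	0.53096766263	0.503250157687	0.522301352243	0	0.592440109731	0.604948229808	0.653575475127	0.606858017013	0.506756202451	0.377073871579	0.429688772409
s8	0.225852469886	0.264974209713	0.344970801143	0.543080141324	0.438518479885	0.398146984048	0.592440109731	0	0.473086808466	0.231126431614	0.326728268937	0.363194143499	0.299615048471	0.562312514091
s9	0.597221718213	0.578722210972	0.605830191994	0.626639615772	0.631550148617	0.569993453258	0.604948229808	0.473086808466	0	0.665843987111	0.394843024628	0.397245323855	0.434655897229	0.69630615772
s10	0.277365547967	0.235297768439	0.301397311771	0.608687385207	0.466802556302	0.576365863081	0.653575475127	0.231126431614	0.665843987111	0	0.483504607231	0.538411554223	0.449723785349	0.678763360062
s11	0.528553057623	0.491048286113	0.632744866937	0.694829244913	0.539765952436	0.433367540712	0.606858017013	0.326728268937	0.394843024628	0.483504607231	0	0.491603269945	0.432429148889	0.585049554858
s12	0.436533293762	0.459440859332	0.472464191245	0.463209687832	0.46686107764	0.482267692038	0.506756202451	0.363194143499	0.397245323855	0.538411554223	0.491603269945	0	0.269045774942	0.666237487993
s13	0.291335789592	0.266301994256	0.393039288833	0.421278678832	0.456886335117	0.278852116252	0.377073871579	0.299615048471	0.434655897229	0.449723785349	0.432429148889	0.269045774942	0	0.474409060934
s14	0.534655267839	0.503654278892	0.533882036897	0.708177250009	0.685821465555	0.300774593138	0.429688772409	0.562312514091	0.69630615772	0.678763360062	0.585049554858	0.666237487993	0.474409060934	0
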